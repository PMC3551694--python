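"""24-variant pigmentation panel: marker definitions, genotype profiles,
replicate consensus and dosage encoding.

The panel couples a SNaPshot-style multiplex of 24 eye/hair-colour
predictive DNA variants (11 in *MC1R*, plus single variants in *HERC2*,
*IRF4*, *TYR*, *EXOC2*, *SLC45A2*, *TYRP1*, *OCA2*, *SLC24A4*, *KITLG* and
*ASIP*) with genotype bookkeeping suited to degraded skeletal material:
profiles are typed in replicate, merged under drop-out-aware consensus
rules, and encoded as effect-allele dosages for the prediction models.

Genotype strings follow the assay dialect: a single letter is a homozygote
("C"), two letters joined by a slash a heterozygote ("G/T"), and "-" a
missing call.  Insertion (N29insA) and premature-stop (Y152OCH) variants are
treated as ordinary biallelic markers with symbolic alleles, since only the
effect-allele count matters downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

PANEL_SIZE = 24
#: Size of the eye-colour marker subset (the six-SNP eye model).
EYE_MODEL_SIZE = 6
#: Default relative-signal detection threshold below which a call is treated
#: as missing before consensus merging.  Stands in for an instrument-level
#: peak-height limit (RFU), which is not portable across platforms.
DETECTION_THRESHOLD = 0.05

EYE_MODEL_MARKERS = frozenset(
    {"rs12913832", "rs1800407", "rs12896399", "rs16891982", "rs1393350", "rs12203592"}
)


class PanelConfigError(ValueError):
    """Raised when a panel configuration violates the panel contract."""


class ProfileParseError(ValueError):
    """Raised when a genotype record cannot be parsed against the panel."""


class ConsensusStatus(str, Enum):
    CONSISTENT = "consistent"
    DROPOUT_RESOLVED = "dropout_resolved"
    DISCORDANT = "discordant"
    MISSING = "missing"


@dataclass(frozen=True)
class MarkerDef:
    """One panel variant and its role in the prediction models."""

    marker_id: str
    gene: str
    assay_index: int
    alleles: tuple[str, ...]
    effect_allele: str
    in_eye_model: bool = False
    in_hair_model: bool = True
    in_shade_model: bool = True
    red_penetrant: bool = False
    dropout_sensitivity: float = 1.0
    effect_allele_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.effect_allele not in self.alleles:
            raise PanelConfigError(
                f"{self.marker_id}: effect allele {self.effect_allele!r} "
                f"not in allele set {self.alleles}"
            )
        if self.dropout_sensitivity <= 0:
            raise PanelConfigError(f"{self.marker_id}: dropout_sensitivity must be > 0")


@dataclass(frozen=True)
class AlleleCall:
    """Observed alleles at one marker; empty tuple means missing.

    ``signal`` is an optional relative peak intensity in [0, 1] used by the
    degradation simulator and QC threshold; real casework tables carry no
    signal and leave it None.
    """

    marker_id: str
    alleles: tuple[str, ...] = ()
    signal: float | None = None

    @property
    def is_missing(self) -> bool:
        return len(self.alleles) == 0

    def genotype(self) -> frozenset[str]:
        """Unordered genotype as an allele set (empty if missing)."""
        return frozenset(self.alleles)

    @property
    def is_het(self) -> bool:
        return len(set(self.alleles)) == 2


@dataclass
class ReplicateProfile:
    """One genotyping run of one sample across the full panel."""

    sample_id: str
    replicate_id: int
    calls: dict[str, AlleleCall]
    template_pg: float | None = None

    def __post_init__(self) -> None:
        if len(self.calls) != PANEL_SIZE:
            raise ProfileParseError(
                f"{self.sample_id} rep {self.replicate_id}: expected "
                f"{PANEL_SIZE} calls, got {len(self.calls)}"
            )


@dataclass
class ConsensusProfile:
    """Per-sample genotype merged across replicates, with per-marker status."""

    sample_id: str
    calls: dict[str, AlleleCall]
    status: dict[str, ConsensusStatus]
    n_replicates: int
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# panel loading


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("evcolor").joinpath("data", name)))


def load_panel(config: str | Path | Mapping | None = None) -> list[MarkerDef]:
    """Load and validate the marker panel, ordered by assay index.

    ``config`` may be a YAML path, an already-parsed mapping, or None for the
    bundled default panel.  Raises :class:`PanelConfigError` on a wrong
    marker count, duplicate ids, a bad effect allele, a non-contiguous assay
    order, or an eye-model subset that is not the canonical six SNPs.
    """
    if config is None:
        config = _data_path("panel.yaml")
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    raw = config["markers"]
    hair_excluded = set(config.get("hair_excluded", ()))
    markers: list[MarkerDef] = []
    for entry in raw:
        entry = dict(entry)
        mid = entry["marker_id"]
        entry["alleles"] = tuple(str(a) for a in entry["alleles"])
        entry.setdefault("in_eye_model", False)
        entry["in_hair_model"] = mid not in hair_excluded
        entry["in_shade_model"] = mid not in hair_excluded
        markers.append(MarkerDef(**entry))

    if len(markers) != PANEL_SIZE:
        raise PanelConfigError(f"panel must define {PANEL_SIZE} markers, got {len(markers)}")
    ids = [m.marker_id for m in markers]
    if len(set(ids)) != PANEL_SIZE:
        raise PanelConfigError("duplicate marker_id in panel configuration")
    if sorted(m.assay_index for m in markers) != list(range(1, PANEL_SIZE + 1)):
        raise PanelConfigError("assay_index values must be a permutation of 1..24")
    eye = {m.marker_id for m in markers if m.in_eye_model}
    if eye != EYE_MODEL_MARKERS:
        raise PanelConfigError(f"eye-model subset must be {sorted(EYE_MODEL_MARKERS)}, got {sorted(eye)}")
    n_hair = sum(m.in_hair_model for m in markers)
    if n_hair != PANEL_SIZE - 2:
        raise PanelConfigError(f"hair model must use 22 markers, got {n_hair}")

    return sorted(markers, key=lambda m: m.assay_index)


def marker_map(panel: Sequence[MarkerDef]) -> dict[str, MarkerDef]:
    return {m.marker_id: m for m in panel}


def model_markers(panel: Sequence[MarkerDef], task: str) -> list[MarkerDef]:
    """Marker subset for a prediction task, in assay order."""
    attr = {"eye": "in_eye_model", "hair": "in_hair_model", "shade": "in_shade_model"}[task]
    return [m for m in panel if getattr(m, attr)]


# ---------------------------------------------------------------------------
# genotype parsing and serialization


def parse_genotype(value: str, marker: MarkerDef, sample_id: str = "?") -> AlleleCall:
    value = value.strip()
    if value in ("-", ""):
        return AlleleCall(marker.marker_id)
    parts = tuple(value.split("/"))
    if len(parts) == 1:
        alleles = (parts[0], parts[0])
    elif len(parts) == 2:
        alleles = parts
    else:
        raise ProfileParseError(f"{sample_id}/{marker.marker_id}: malformed genotype {value!r}")
    for a in set(alleles):
        if a not in marker.alleles:
            raise ProfileParseError(
                f"{sample_id}/{marker.marker_id}: allele {a!r} not in allele set {marker.alleles}"
            )
    return AlleleCall(marker.marker_id, alleles)


def format_genotype(call: AlleleCall) -> str:
    if call.is_missing:
        return "-"
    a, b = call.alleles
    return a if a == b else f"{a}/{b}"


def parse_profile(
    row: Mapping[str, str],
    panel: Sequence[MarkerDef],
    *,
    sample_id: str | None = None,
    replicate_id: int = 1,
    template_pg: float | None = None,
) -> ReplicateProfile:
    """Build a replicate profile from one raw genotype record.

    ``row`` maps marker ids (plus optionally ``sample_id``, ``replicate_id``,
    ``template_pg``) to field strings in the assay dialect.
    """
    sid = sample_id if sample_id is not None else str(row["sample_id"])
    rid = int(row.get("replicate_id", replicate_id))
    tpl = row.get("template_pg", template_pg)
    if isinstance(tpl, str):
        tpl = None if tpl.strip().upper() in ("U", "", "-") else float(tpl)
    calls = {}
    for m in panel:
        if m.marker_id not in row:
            raise ProfileParseError(f"{sid}: no column for marker {m.marker_id}")
        calls[m.marker_id] = parse_genotype(str(row[m.marker_id]), m, sid)
    return ReplicateProfile(sid, rid, calls, tpl)


# ---------------------------------------------------------------------------
# genotype table I/O (tab-separated, assay dialect)


def read_genotype_table(path: str | Path, panel: Sequence[MarkerDef]) -> list[ReplicateProfile]:
    """Read a replicate genotype TSV.

    Expected header: ``sample_id  replicate_id  template_pg  <24 marker
    columns in assay order>``; lines starting with ``#`` are comments.
    """
    profiles = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            profiles.append(parse_profile(row, panel))
    if header is None:
        raise ProfileParseError(f"{path}: empty genotype table")
    return profiles


def write_genotype_table(
    profiles: Iterable[ReplicateProfile], path: str | Path, panel: Sequence[MarkerDef]
) -> None:
    cols = ["sample_id", "replicate_id", "template_pg"] + [m.marker_id for m in panel]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in profiles:
            tpl = "U" if p.template_pg is None else f"{p.template_pg:g}"
            row = [p.sample_id, str(p.replicate_id), tpl]
            row += [format_genotype(p.calls[m.marker_id]) for m in panel]
            fh.write("\t".join(row) + "\n")


def read_vcf(path: str | Path, panel: Sequence[MarkerDef]) -> list[ReplicateProfile]:
    """Minimal VCF ingestion: biallelic records matched to panel markers by
    rs ID only; panel markers without a matching record become missing.

    Allele letters must already be on the assay read-out strand (no strand
    flipping is attempted); an out-of-set allele is a parse error.  Returns
    one single-replicate profile per VCF sample.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    by_id = marker_map(panel)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    genotypes: dict[str, dict[str, AlleleCall]] = {
        s: {m.marker_id: AlleleCall(m.marker_id) for m in panel} for s in samples
    }
    for rec in vcf:
        marker = by_id.get(rec.ID)
        if marker is None or len(rec.ALT) != 1:
            continue
        letters = [rec.REF, rec.ALT[0]]
        for s_idx, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            alleles = (letters[a], letters[b])
            for al in set(alleles):
                if al not in marker.alleles:
                    raise ProfileParseError(
                        f"{samples[s_idx]}/{marker.marker_id}: VCF allele {al!r} "
                        f"not in allele set {marker.alleles}"
                    )
            genotypes[samples[s_idx]][marker.marker_id] = AlleleCall(
                marker.marker_id, alleles
            )
    return [ReplicateProfile(s, 1, genotypes[s]) for s in samples]


# ---------------------------------------------------------------------------
# consensus merging


def _canonical_call(marker: MarkerDef, genotype: frozenset[str]) -> AlleleCall:
    """Consensus call with alleles in the marker's configured order."""
    ordered = tuple(a for a in marker.alleles if a in genotype)
    if len(ordered) == 1:
        ordered = (ordered[0], ordered[0])
    return AlleleCall(marker.marker_id, ordered)


def consensus_merge(
    replicates: Sequence[ReplicateProfile],
    panel: Sequence[MarkerDef],
    detection_threshold: float = DETECTION_THRESHOLD,
) -> ConsensusProfile:
    """Merge replicate typings of one sample into a consensus profile.

    Per marker: identical calls are ``consistent``; a heterozygote in at
    least one replicate together with a compatible homozygote elsewhere is
    resolved to the heterozygote (``dropout_resolved`` — drop-out of one
    allele being more likely than drop-in of a foreign one, although the
    latter cannot be excluded, so a flag is recorded); two incompatible
    non-missing genotypes yield ``discordant`` with a missing consensus.
    Calls with a relative signal below ``detection_threshold`` are demoted to
    missing before merging.
    """
    if not replicates:
        raise ValueError("consensus_merge requires at least one replicate")
    sids = {r.sample_id for r in replicates}
    if len(sids) > 1:
        raise ValueError(f"consensus_merge: mixed sample ids {sorted(sids)}")
    sid = replicates[0].sample_id

    by_marker = marker_map(panel)
    calls: dict[str, AlleleCall] = {}
    status: dict[str, ConsensusStatus] = {}
    flags: list[str] = []

    for m in panel:
        mid = m.marker_id
        genotypes: list[frozenset[str]] = []
        for rep in replicates:
            call = rep.calls[mid]
            if call.is_missing:
                continue
            if call.signal is not None and call.signal < detection_threshold:
                continue
            genotypes.append(call.genotype())

        distinct = set(genotypes)
        if not distinct:
            calls[mid] = AlleleCall(mid)
            status[mid] = ConsensusStatus.MISSING
            continue
        if len(distinct) == 1:
            calls[mid] = _canonical_call(by_marker[mid], next(iter(distinct)))
            status[mid] = ConsensusStatus.CONSISTENT
            continue
        hets = [g for g in distinct if len(g) == 2]
        homs = [g for g in distinct if len(g) == 1]
        if len(hets) == 1 and all(h <= hets[0] for h in homs):
            calls[mid] = _canonical_call(by_marker[mid], hets[0])
            status[mid] = ConsensusStatus.DROPOUT_RESOLVED
            flags.append(f"dropout_resolved:{mid} (drop-in cannot be excluded)")
        else:
            calls[mid] = AlleleCall(mid)
            status[mid] = ConsensusStatus.DISCORDANT
            flags.append(f"discordant:{mid}")

    return ConsensusProfile(sid, calls, status, n_replicates=len(replicates), flags=flags)


def completeness(profile: ConsensusProfile) -> tuple[int, bool, list[str]]:
    """Number of called markers, full-profile flag, and missing marker ids."""
    missing = [mid for mid, call in profile.calls.items() if call.is_missing]
    n_called = len(profile.calls) - len(missing)
    return n_called, n_called == PANEL_SIZE, missing


def consensus_as_replicate(profile: ConsensusProfile, replicate_id: int = 1) -> ReplicateProfile:
    """View a consensus profile as a single replicate (for re-merging or I/O)."""
    return ReplicateProfile(profile.sample_id, replicate_id, dict(profile.calls), None)


# ---------------------------------------------------------------------------
# dosage encoding


def encode_dosage(
    profile: ConsensusProfile, task: str, panel: Sequence[MarkerDef]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Effect-allele dosages for one prediction task.

    Returns ``(dosages, missing_mask, marker_ids)`` over the task's marker
    subset in assay order.  Missing markers get dosage 0 with the mask set;
    imputation is the caller's (policy's) responsibility.
    """
    subset = model_markers(panel, task)
    dosages = np.zeros(len(subset), dtype=float)
    mask = np.zeros(len(subset), dtype=bool)
    for j, m in enumerate(subset):
        call = profile.calls[m.marker_id]
        if call.is_missing:
            mask[j] = True
        else:
            dosages[j] = sum(1 for a in call.alleles if a == m.effect_allele)
    return dosages, mask, [m.marker_id for m in subset]


__all__ = [
    "PANEL_SIZE",
    "EYE_MODEL_MARKERS",
    "DETECTION_THRESHOLD",
    "MarkerDef",
    "AlleleCall",
    "ReplicateProfile",
    "ConsensusProfile",
    "ConsensusStatus",
    "PanelConfigError",
    "ProfileParseError",
    "load_panel",
    "marker_map",
    "model_markers",
    "parse_genotype",
    "format_genotype",
    "parse_profile",
    "read_genotype_table",
    "write_genotype_table",
    "consensus_merge",
    "consensus_as_replicate",
    "completeness",
    "encode_dosage",
]
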