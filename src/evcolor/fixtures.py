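"""Bundled study fixtures: the published 26-sample genotype table and the
published prediction-result table, transcribed verbatim.

The two tables are immutable test assets guarded by checksums; the loader
refuses to return silently corrupted transcriptions.  The genotype table
carries per-sample age class and the starting template DNA amount exactly
as printed (the printed column header says ng while the accompanying text
discusses per-reaction amounts in pg; numbers are stored verbatim, with "U"
for the two samples whose DNA amount was undeterminable due to PCR
inhibition).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .model import ModelError, ProbabilityVector
from .panel import (
    MarkerDef,
    ReplicateProfile,
    _data_path,
    load_panel,
    parse_profile,
)

TABLE1_SHA256 = "3b404d8c914ee8ae936b474d6259a592680a101daec73bdb25267f271a1e37b5"
TABLE2_SHA256 = "e176322e55e594ca4d1a99ec24372aaf5d384fa5cdbe9c8ad8166eb155bb887e"


class FixtureError(RuntimeError):
    pass


@dataclass
class Table1Row:
    profile: ReplicateProfile
    age_class: str
    template_raw: str          # verbatim printed value ("U" = undeterminable)


@dataclass
class Table2Row:
    """Published per-sample prediction results, with the printed calls and
    accuracies attached as oracle fields.  Hair fields are None for the
    sample whose hair prediction was withheld."""

    sample_id: str
    eye_probs: ProbabilityVector
    eye_call: str
    eye_accuracy: float
    hair_probs: ProbabilityVector | None
    shade_probs: ProbabilityVector | None
    hair_call: str | None
    hair_accuracy: float | None


def _read_checked(name: str, expected_sha: str) -> list[str]:
    path = _data_path(name)
    blob = path.read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != expected_sha:
        raise FixtureError(f"fixture {name} checksum mismatch: {digest}")
    return [ln for ln in blob.decode().splitlines() if ln and not ln.startswith("#")]


def _rows(lines: list[str]) -> list[dict[str, str]]:
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def load_fixture_table1(
    panel: list[MarkerDef] | None = None,
) -> list[Table1Row]:
    """The 26 published genotype profiles, one replicate-level profile per
    sample (the study typed every sample at least twice but prints the
    merged result; it is loaded here as a single replicate)."""
    if panel is None:
        panel = load_panel()
    rows = []
    for row in _rows(_read_checked("table1.tsv", TABLE1_SHA256)):
        profile = parse_profile(row, panel, sample_id=row["sample_id"])
        rows.append(Table1Row(profile, row["age_class"], row["template"]))
    if len(rows) != 26:
        raise FixtureError(f"expected 26 genotype rows, got {len(rows)}")
    return rows


def load_fixture_table2() -> list[Table2Row]:
    """The 26 published prediction rows: probability vectors plus printed
    labels and accuracies (26 eye entries; 25 hair/shade entries)."""
    out = []
    for row in _rows(_read_checked("table2.tsv", TABLE2_SHA256)):
        sid = row["sample_id"]
        try:
            eye = ProbabilityVector(
                "eye",
                {
                    "blue": float(row["eye_blue"]),
                    "intermediate": float(row["eye_intermediate"]),
                    "brown": float(row["eye_brown"]),
                },
            )
        except ModelError as exc:
            raise FixtureError(f"{sid}: eye fixture normalization violation: {exc}") from exc
        if row["hair_call"] == "-":
            hair = shade = None
            hair_call = hair_acc = None
        else:
            try:
                hair = ProbabilityVector(
                    "hair",
                    {
                        "blond": float(row["hair_blond"]),
                        "brown": float(row["hair_brown"]),
                        "red": float(row["hair_red"]),
                        "black": float(row["hair_black"]),
                    },
                )
                shade = ProbabilityVector(
                    "shade",
                    {"light": float(row["shade_light"]), "dark": float(row["shade_dark"])},
                )
            except ModelError as exc:
                raise FixtureError(f"{sid}: hair fixture normalization violation: {exc}") from exc
            hair_call = row["hair_call"]
            hair_acc = float(row["hair_accuracy"])
        out.append(
            Table2Row(
                sample_id=sid,
                eye_probs=eye,
                eye_call=row["eye_call"],
                eye_accuracy=float(row["eye_accuracy"]),
                hair_probs=hair,
                shade_probs=shade,
                hair_call=hair_call,
                hair_accuracy=hair_acc,
            )
        )
    if len(out) != 26:
        raise FixtureError(f"expected 26 prediction rows, got {len(out)}")
    return out


def serialize_table1(rows: list[Table1Row], panel: list[MarkerDef] | None = None) -> str:
    """Re-serialize parsed genotype rows in the fixture dialect (used by the
    byte-identity round-trip check)."""
    from .panel import format_genotype

    if panel is None:
        panel = load_panel()
    cols = ["sample_id", "age_class", "template"] + [m.marker_id for m in panel]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append(
            "\t".join(
                [r.profile.sample_id, r.age_class, r.template_raw]
                + [format_genotype(r.profile.calls[m.marker_id]) for m in panel]
            )
        )
    return "\n".join(lines)


__all__ = [
    "FixtureError",
    "Table1Row",
    "Table2Row",
    "load_fixture_table1",
    "load_fixture_table2",
    "serialize_table1",
    "TABLE1_SHA256",
    "TABLE2_SHA256",
]
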