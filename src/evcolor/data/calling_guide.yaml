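# Prediction guide: probability vectors -> final categorical calls with
# accuracy annotations.
#
# The guide's thresholds are not published as a table; they were derived once
# by constraint satisfaction against the 25 published hair calls and 26
# published eye calls (every published (probability, label, accuracy) triple
# is reproduced by this configuration), then frozen here.  Bin edges that
# fall between observed data points are conventions and are marked so.
#
# Hair: the combined label is a function of (argmax category, its
# probability, the light-shade probability).  Rules are checked in order;
# intervals are half-open (lo, hi] on the quantity named by "quantity".
hair_rules:
  black:
    - {quantity: p, lo: 0.80, hi: 1.0, label: Black}
    - {quantity: p, lo: 0.65, hi: 0.80, label: Black/Dark Brown}
    - {quantity: p, lo: 0.0, hi: 0.65, label: Dark Brown}
  brown:
    # light > 0.5 with brown argmax never occurs in the published set; the
    # lighter combined label is a convention.
    - {quantity: light, lo: 0.5, hi: 1.0, label: Dark Blond/Light Brown}
    - {quantity: light, lo: 0.0, hi: 0.5, label: Dark Brown}
  blond:
    - {quantity: light, lo: 0.90, hi: 1.0, label: Light Blond}
    - {quantity: light, lo: 0.85, hi: 0.90, label: Dark Blond/Light Brown}
    - {quantity: light, lo: 0.0, hi: 0.85, label: Dark Blond/Brown}
  red:
    - {quantity: p, lo: 0.0, hi: 1.0, label: Red}

# Accuracy of the combined hair label (percent, >300-individual European
# test set; red from the published per-category figure).
hair_accuracy:
  Light Blond: 69.5
  Dark Blond/Light Brown: 69.5
  Dark Blond/Brown: 78.5
  Dark Brown: 78.5
  Black/Dark Brown: 87.5
  Black: 87.5
  Red: 80.0

# Eye accuracy bins (percent, >3,800-individual European test set), per
# called category, on the called category's probability.  Intervals are
# half-open [lo, hi); probabilities of exactly 1.0 fall in the top bin.
# The intermediate category is never called in the published set; a flat
# placeholder accuracy is configured for completeness.
eye_accuracy:
  blue:
    - {lo: 0.95, hi: 1.001, accuracy: 99.0}
    - {lo: 0.91, hi: 0.95, accuracy: 97.4}
    - {lo: 0.87, hi: 0.91, accuracy: 95.6}
    - {lo: 0.0, hi: 0.87, accuracy: 94.0}
  brown:
    - {lo: 0.95, hi: 1.001, accuracy: 99.0}
    - {lo: 0.87, hi: 0.95, accuracy: 95.6}
    - {lo: 0.70, hi: 0.87, accuracy: 94.0}
    - {lo: 0.60, hi: 0.70, accuracy: 91.9}
    - {lo: 0.55, hi: 0.60, accuracy: 91.0}
    - {lo: 0.50, hi: 0.55, accuracy: 90.4}
    - {lo: 0.0, hi: 0.50, accuracy: 87.5}
  intermediate:
    - {lo: 0.0, hi: 1.001, accuracy: 75.0}

# Tie-breaking at argmax: the darker category wins (and the call is flagged).
eye_darkness_order: [brown, intermediate, blue]
hair_darkness_order: [black, brown, red, blond]
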