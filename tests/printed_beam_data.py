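"""Published beam-commissioning values used as test inputs.

PDD rows: (energy, field size cm, source) -> (d_max cm, PDD5, PDD10, PDD20,
published D20/D5 ratio). Only rows whose published ratio equals
round(PDD20/PDD5, 3) are listed here, so the ratio can be re-derived by
arithmetic; a few published rows disagree with their own PDD entries at the
third decimal and are excluded.
"""

# self-consistent PDD rows
PDD_ROWS = {
    ("6MV", 5, "code_a"): (1.4, 89.5, 71.4, 36.8, 0.411),
    ("6MV", 10, "code_a"): (1.4, 90.1, 72.2, 37.4, 0.415),
    ("6MV", 20, "code_a"): (1.4, 90.8, 73.0, 38.1, 0.420),
    ("6MV", 5, "code_b"): (1.4, 89.8, 71.7, 37.1, 0.413),
    ("6MV", 10, "code_b"): (1.4, 90.4, 72.5, 37.7, 0.417),
    ("6MV", 20, "code_b"): (1.4, 91.1, 73.3, 38.4, 0.422),
    ("6MV", 30, "measurement"): (1.4, 91.5, 73.8, 38.9, 0.425),
    ("12MV", 5, "code_a"): (2.5, 94.3, 78.8, 46.5, 0.493),
    ("12MV", 10, "code_a"): (2.5, 94.8, 79.6, 47.1, 0.497),
    ("12MV", 30, "code_a"): (2.5, 95.8, 80.9, 48.4, 0.505),
    ("12MV", 10, "measurement"): (2.5, 95.0, 79.8, 47.3, 0.498),
    ("12MV", 40, "code_b"): (2.5, 96.5, 81.7, 49.3, 0.511),
}

# relative wedge factors per (energy, source) over field sizes 5..40 cm
WEDGE_FIELDS = [5.0, 10.0, 20.0, 30.0, 40.0]
WEDGE_FACTORS = {
    ("6MV", "code_a"): [0.686, 0.695, 0.711, 0.726, 0.740],
    ("6MV", "code_b"): [0.689, 0.698, 0.715, 0.731, 0.745],
    ("12MV", "code_a"): [0.670, 0.680, 0.700, 0.718, 0.735],
    ("12MV", "code_b"): [0.673, 0.683, 0.704, 0.723, 0.740],
}

# 6 MV in-plane flatness (%) at 10 cm depth per field size
FLATNESS_FIELDS = [5.0, 10.0, 20.0, 30.0, 40.0]
FLATNESS_6MV_INPLANE = {
    "code_a": [105.05, 105.42, 105.53, 105.55, 105.60],
    "code_b": [105.06, 105.45, 105.56, 105.58, 105.62],
}
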