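"""Annotate observed accurate masses against the bundled compound library.

Queries a few published discriminant-variable masses (creatinine, hydrogen
phosphate, TMAO, the leucine/isoleucine set) as M+H / M+Na / M+H-H2O adduct
ions within a +/-10 ppm window and prints each hit with its signed mass
error and MSI confidence level (3 = accurate-mass-only match, 4 = unknown).
"""
from metabopair import annotate_features, default_library_path, read_compound_library

library = read_compound_library(default_library_path())
observed = [
    ("creatinine-like", 136.0485),
    ("phosphate-like", 98.98454),
    ("tmao-like", 76.07599),
    ("leucine-like", 114.0919),
    ("nothing-at-all", 500.0000),
]
hits = annotate_features(observed, library, tolerance_ppm=10.0)
print(hits[["feature_id", "observed_mz", "compound", "formula", "adduct",
            "ppm_error", "msi_level"]].round(4).to_string(index=False))
# Every printed mass finds its compound well inside 10 ppm; 114.0919 shows
# the classic water-loss degeneracy (C6H11NO M+H vs C6H13NO2 M+H-H2O have
# identical theoretical m/z), and the 500 Da probe stays an MSI-level-4
# unknown.
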