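"""Bundled reference data.

The hen egg white lysozyme (HEWL) residue-pKa benchmark: published
predictions from 10 ns adiabatic constant-pH runs and from the standard
GROMACS CpHMD baseline (10 and 50 ns), against experimental NMR values.
Replicate standard deviations are over three independent simulations.
Used to validate :func:`phafed.analysis.prediction_metrics` against the
published error metrics (MUE 0.60 / RMSE 0.68 for the adiabatic runs and
MUE 0.96 for the 10 ns baseline).
"""

import pandas as pd

_HEWL_ROWS = [
    # residue, pH-AFED 10ns, std, std CpHMD 10ns, std, std CpHMD 50ns, std, exp
    ("Glu-7",   3.27, 0.06, 2.60, 0.16, 2.64, 0.07, 2.60),
    ("His-15",  5.14, 0.04, 4.95, 0.14, 4.68, 0.00, 5.50),
    ("Asp-18",  3.13, 0.10, 3.07, 0.35, 3.42, 0.15, 2.80),
    ("Glu-35",  6.49, 0.27, 8.56, 0.50, 8.01, 0.89, 6.10),
    ("Asp-48",  2.07, 0.47, 0.37, 0.67, 1.35, 0.53, 1.40),
    ("Asp-52",  5.03, 0.02, 5.73, 0.51, 5.62, 0.00, 3.60),
    ("Asp-66",  1.96, 0.07, -0.08, 0.66, 1.52, 0.01, 1.20),
    ("Asp-87",  2.75, 0.03, 2.14, 0.36, 1.96, 0.07, 2.20),
    ("Asp-101", 4.90, 0.11, 5.37, 0.36, 5.34, 0.00, 4.50),
    ("Asp-119", 3.01, 0.07, 2.57, 0.37, 2.94, 0.17, 3.50),
]


def hewl_benchmark() -> pd.DataFrame:
    """HEWL per-residue pKa benchmark as a DataFrame.

    Columns: residue, ph_afed_10ns (+_std), standard_10ns (+_std),
    standard_50ns (+_std), experimental.
    """
    return pd.DataFrame(
        _HEWL_ROWS,
        columns=[
            "residue",
            "ph_afed_10ns", "ph_afed_10ns_std",
            "standard_10ns", "standard_10ns_std",
            "standard_50ns", "standard_50ns_std",
            "experimental",
        ],
    )
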