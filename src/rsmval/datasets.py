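"""Reference data from the published 43-drug QuEChERS/UPLC-MS/MS study.

These are the published summary results of a Box-Behnken optimisation of a
three-sorbent d-SPE clean-up (C18, PSA, Z-Sep+) for 43 quinolone and
sulfonamide residues in bacon and ham, validated to the 2002/657/EC
framework.  The raw 17-run response and the per-analyte recovery tables were
not published; what is reproducible from the printed summaries — the
regression coefficients, the aggregate residual/pure-error sums of squares
and the per-compound decision limits — is shipped here as worked-example
inputs and cross-check targets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import FactorSpec, generate_bbd
from .model import QuadraticModel

__all__ = [
    "reference_surface",
    "reference_error_ss",
    "reference_design",
    "validation_limits",
    "REFERENCE_VL",
]

#: Validation level of the published study, ug/kg.
REFERENCE_VL = 50.0


def reference_surface() -> QuadraticModel:
    """The published second-order surface for the compliant-drug count.

    Coefficients are in coded units for factors A = C18, B = PSA,
    C = Z-Sep+ (sorbent masses):

        Y = 41.80 - 0.50 A - 1.50 B - 2.75 C - 0.50 AB + 1.00 AC + 0.00 BC
            - 7.90 A^2 - 8.40 B^2 - 2.90 C^2
    """
    return QuadraticModel(
        intercept=41.80,
        linear=(-0.50, -1.50, -2.75),
        interaction=(-0.50, 1.00, 0.00),
        quadratic=(-7.90, -8.40, -2.90),
    )


def reference_error_ss() -> tuple[float, float]:
    """Published aggregate error components: (residual SS, pure-error SS).

    Residual SS 11.3 on 7 df; pure-error SS 2.8 on the 4 df of the five
    centre replicates.
    """
    return 11.3, 2.8


def reference_design():
    """The study's design: BBD(3) with 5 centre points, 17 runs.

    The actual mg levels assigned to coded -1/0/+1 were not published, so the
    factor specs here are placeholders spanning plausible sorbent masses;
    every statistic computed on the coded scale is unaffected by them.
    """
    specs = (
        FactorSpec("C18", 100.0, 300.0),
        FactorSpec("PSA", 100.0, 300.0),
        FactorSpec("Z-Sep+", 25.0, 75.0),
    )
    return generate_bbd(specs, n_center=5)


def validation_limits() -> pd.DataFrame:
    """Published per-compound CCalpha, CCbeta and LOQ for bacon and ham.

    Columns: compound, group (quinolone/sulfonamide), matrix (bacon/ham),
    cc_alpha_ugkg, cc_beta_ugkg, loq_ugkg.  43 compounds x 2 matrices.
    """
    with resources.files("rsmval").joinpath("data/validation_limits.csv").open() as fh:
        return pd.read_csv(fh)
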