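"""Inter-rater segmentation agreement via pixelwise Cohen's kappa.

Two clinicians segment the same compartment independently; agreement beyond
chance between the two binary masks is summarised by Cohen's kappa over all
image pixels, kappa = (p_o - p_e) / (1 - p_e), with the 2x2 agreement table
returned alongside so alternative supports can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import ROIMask

__all__ = ["KappaResult", "cohen_kappa", "DegenerateAgreementError"]


class DegenerateAgreementError(ValueError):
    """Expected agreement p_e = 1: kappa undefined (both raters constant)."""


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    table: np.ndarray   # 2x2 counts, rows = rater A (out, in), cols = rater B
    p_observed: float
    p_expected: float


def cohen_kappa(mask_a: ROIMask | np.ndarray, mask_b: ROIMask | np.ndarray) -> KappaResult:
    """Chance-corrected agreement of two binary masks over all pixels.

    kappa = 1 for identical masks, 0 at chance level, -1 for complementary
    half/half masks. Raises DegenerateAgreementError when both raters give
    the same constant label everywhere (p_e = 1).
    """
    a = (mask_a.mask if isinstance(mask_a, ROIMask) else np.asarray(mask_a, dtype=bool))
    b = (mask_b.mask if isinstance(mask_b, ROIMask) else np.asarray(mask_b, dtype=bool))
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    n = a.size
    both = int(np.sum(a & b))
    only_a = int(np.sum(a & ~b))
    only_b = int(np.sum(~a & b))
    neither = n - both - only_a - only_b
    table = np.array([[neither, only_b], [only_a, both]], dtype=np.int64)

    p_o = (both + neither) / n
    pa_in, pb_in = (both + only_a) / n, (both + only_b) / n
    p_e = pa_in * pb_in + (1 - pa_in) * (1 - pb_in)
    if p_e == 1.0:
        raise DegenerateAgreementError(
            "both raters assign one constant label with identical marginals; "
            "kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), table=table,
                       p_observed=float(p_o), p_expected=float(p_e))
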