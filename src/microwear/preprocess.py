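"""S-F surface preparation: levelling and polynomial form removal.

Texture parameters are computed on the S-F surface: the primary surface after
the F-operator (form removal).  The F-operator here is a least-squares 2-D
polynomial of configurable total degree (default 2), fitted to the valid
points only; the fitted form is subtracted everywhere (also under masked
points, so later gap filling stays consistent), and the valid-point mean is
removed so that downstream height parameters see a zero-mean surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError
from .surface_io import HeightMap


@dataclass
class PreprocessSettings:
    """F-operator configuration.

    form_degree: total degree of the least-squares polynomial form (0-3).
    level: also remove the best-fit plane when form_degree < 1 (kept for
        symmetry with instrument templates; degree >= 1 subsumes it).
    center: subtract the valid-point mean after form removal.
    """

    form_degree: int = 2
    level: bool = True
    center: bool = True

    def __post_init__(self):
        if self.form_degree not in (0, 1, 2, 3):
            raise ValueError("form_degree must be in {0, 1, 2, 3}")


def _poly_terms(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of monomials x^i y^j with i + j <= degree."""
    cols = [x**i * y**j for d in range(degree + 1) for i, j in
            [(i, d - i) for i in range(d + 1)]]
    return np.column_stack(cols)


def _fit_poly(hm: HeightMap, degree: int) -> np.ndarray:
    """Least-squares polynomial form evaluated on the full grid."""
    nrows, ncols = hm.shape
    # normalised coordinates keep the Vandermonde matrix well conditioned
    y, x = np.mgrid[0:nrows, 0:ncols]
    xn = (x / (ncols - 1)) * 2.0 - 1.0
    yn = (y / (nrows - 1)) * 2.0 - 1.0
    v = hm.valid
    n_terms = (degree + 1) * (degree + 2) // 2
    if v.sum() < n_terms:
        raise ComputationError(
            f"form removal needs at least {n_terms} valid points, have {int(v.sum())}"
        )
    A = _poly_terms(xn[v].ravel(), yn[v].ravel(), degree)
    coef, _, rank, _ = np.linalg.lstsq(A, hm.heights[v].ravel(), rcond=None)
    if rank < n_terms:
        raise ComputationError("degenerate geometry: polynomial fit is rank deficient")
    full = _poly_terms(xn.ravel(), yn.ravel(), degree) @ coef
    return full.reshape(hm.shape)


def level(hm: HeightMap) -> HeightMap:
    """Subtract the least-squares best-fit plane and the residual mean.

    Requires at least three non-collinear valid points; the returned surface
    has zero mean over its valid points.
    """
    form = _fit_poly(hm, degree=1)
    res = hm.heights - form
    res -= res[hm.valid].mean()
    return hm.copy_with(heights=res, levelled=True)


def remove_form(hm: HeightMap, settings: PreprocessSettings | None = None) -> HeightMap:
    """Apply the F-operator: subtract the least-squares polynomial form.

    The residual is centred (zero mean over valid points) when
    ``settings.center`` is on.  Idempotent: the residual of a least-squares
    fit is orthogonal to the polynomial basis.
    """
    settings = settings or PreprocessSettings()
    degree = settings.form_degree
    if degree == 0 and settings.level:
        degree = 1
    if degree == 0:
        res = hm.heights.copy()
    else:
        res = hm.heights - _fit_poly(hm, degree)
    if settings.center:
        res = res - res[hm.valid].mean()
    return hm.copy_with(heights=res, form_degree=settings.form_degree)


def sf_surface(hm: HeightMap, settings: PreprocessSettings | None = None) -> HeightMap:
    """Produce the S-F surface all parameters are computed on."""
    return remove_form(hm, settings)
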