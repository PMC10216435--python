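"""Constrained linear unmixing of tissue spectra.

The linear mixing model writes a measured pixel spectrum as a convex
combination of pure-tissue *endmember* spectra plus noise::

    x = sum_c a_c e_c + eps,   a_c >= 0,   sum_c a_c = 1

with one endmember per tissue class (invasive carcinoma IC, carcinoma in
situ CIS, fat, connective tissue). The fractional *abundances* a_c are
recovered per pixel by constrained least squares; the malignant classes
IC and CIS are summed into a per-pixel tumor fraction that forms the
tumor prediction map of an ink-mark patch.

Two ways of enforcing the sum-to-one constraint are provided:

``"constrained"``
    The exact global minimizer of ||E^T a - x||^2 on the unit simplex
    (fully constrained least squares). For the small class counts used
    here the optimum is found exactly by enumerating active sets: for
    every support S the equality-constrained KKT system is solved and the
    best feasible candidate is kept. This is the textbook FCLS solution.

``"rescaled"`` (default for SNV data)
    Nonnegative least squares without the sum constraint, followed by
    normalization of the coefficients to sum one. SNV normalization
    divides every spectrum by its own standard deviation, so a noiseless
    mixture is an exact *conic* combination of the SNV endmembers whose
    coefficient sum carries the per-pixel scale; dropping the hard sum
    constraint during the solve and renormalizing afterwards recovers the
    true fractions exactly in that geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import nnls

from .errors import BandGridError, IllPosedUnmixingError, ShapeMismatchError
from .hypercube import Hypercube, Spectrum

#: Canonical class order; the first two are the malignant classes.
DEFAULT_CLASSES = ("IC", "CIS", "fat", "connective")
MALIGNANT_CLASSES = ("IC", "CIS")

_ANC_CLAMP = 1e-12  # negative values above this magnitude are solver errors
_ASC_TOL = 1e-6


@dataclass
class EndmemberSet:
    """Pure-tissue spectra, one row per class, on a common band grid.

    ``provenance`` optionally records where each endmember pixel came
    from as ``(mark_id, row, col)`` tuples.
    """

    spectra: np.ndarray  # (C, m)
    classes: tuple[str, ...] = DEFAULT_CLASSES
    wavelengths: np.ndarray | None = None
    provenance: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.classes = tuple(self.classes)
        if len(self.classes) != self.spectra.shape[0]:
            raise ShapeMismatchError(
                f"{len(self.classes)} class names for {self.spectra.shape[0]} spectra"
            )
        if self.spectra.shape[0] < 2:
            raise IllPosedUnmixingError("need at least two endmembers")
        if np.linalg.matrix_rank(self.spectra) < self.spectra.shape[0]:
            raise IllPosedUnmixingError("endmember spectra are linearly dependent")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.size != self.spectra.shape[1]:
                raise ShapeMismatchError("wavelength axis does not match endmember length")

    @property
    def n_classes(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def malignant_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.classes) if c in MALIGNANT_CLASSES])


@dataclass
class AbundanceVector:
    """Per-pixel fractional abundances with the reconstruction residual."""

    values: np.ndarray
    classes: tuple[str, ...]
    residual_norm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.min(self.values) < -_ASC_TOL or abs(self.values.sum() - 1.0) > 1e-5:
            raise ValueError("abundances must be nonnegative and sum to one")


@dataclass
class AbundanceMap:
    """Per-pixel abundances over a patch, plus the derived tumor layer."""

    abundances: np.ndarray  # (H, W, C)
    classes: tuple[str, ...]
    residual_norms: np.ndarray  # (H, W)

    @property
    def tumor_map(self) -> np.ndarray:
        """Per-pixel malignant (IC + CIS) abundance in [0, 1]."""
        idx = [i for i, c in enumerate(self.classes) if c in MALIGNANT_CLASSES]
        return self.abundances[:, :, idx].sum(axis=2)


def extract_endmember(
    cube: Hypercube, mark_center: tuple[int, int], class_name: str
) -> tuple[Spectrum, tuple]:
    """Read the endmember spectrum at the center pixel of a marked location.

    Returns the spectrum together with a provenance record
    ``(class_name, row, col)``.
    """
    row, col = mark_center
    if not (0 <= row < cube.rows and 0 <= col < cube.cols):
        raise IndexError(f"mark center ({row}, {col}) outside {cube.rows}x{cube.cols} image")
    return cube.spectrum_at(row, col), (class_name, int(row), int(col))


def build_endmembers(
    cube: Hypercube, centers: dict[str, tuple[int, int]], classes=DEFAULT_CLASSES
) -> EndmemberSet:
    """Assemble an :class:`EndmemberSet` from marked pure-tissue pixels."""
    spectra, provenance = [], {}
    for name in classes:
        spec, prov = extract_endmember(cube, centers[name], name)
        spectra.append(spec.values)
        provenance[name] = prov
    return EndmemberSet(
        np.array(spectra), tuple(classes), cube.wavelengths.copy(), provenance
    )


def _fcls_simplex(E: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact FCLS optimum on the unit simplex by active-set enumeration.

    The problem min ||E^T a - x||^2 s.t. a >= 0, sum a = 1 is a convex QP;
    its minimizer is the equality-constrained solution on some support with
    nonnegative entries. All supports are enumerated (2^C - 1 for C
    classes, trivial for C <= 6) and the feasible candidate with the
    smallest objective is returned. Vertices are always feasible, so a
    solution always exists.
    """
    C = E.shape[0]
    G = E @ E.T
    h = E @ x
    best_a, best_obj = None, np.inf
    for k in range(1, C + 1):
        for support in combinations(range(C), k):
            S = list(support)
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = G[np.ix_(S, S)]
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            rhs = np.append(h[S], 1.0)
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            a_S = sol[:k]
            if a_S.min() < -1e-9:
                continue
            a = np.zeros(C)
            a[S] = np.clip(a_S, 0.0, None)
            a /= a.sum()
            obj = float(a @ G @ a - 2.0 * a @ h)
            if obj < best_obj - 1e-15 or best_a is None:
                best_obj, best_a = obj, a
    resid2 = max(best_obj + float(x @ x), 0.0)
    return best_a, np.sqrt(resid2)


def _nnls_rescaled(E: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float] | None:
    coeff, resid = nnls(E.T, x)
    total = coeff.sum()
    if total <= 1e-12:
        return None  # degenerate cone fit; caller falls back to the simplex solver
    return coeff / total, float(resid)


def unmix_spectrum(
    x: Spectrum | np.ndarray,
    E: EndmemberSet,
    sum_to_one: str = "rescaled",
) -> AbundanceVector:
    """Estimate the abundance vector of one spectrum.

    Parameters
    ----------
    x:
        Measured spectrum on the same band grid as ``E``.
    E:
        Endmember set (full row rank required).
    sum_to_one:
        ``"constrained"`` for the exact simplex-constrained optimum, or
        ``"rescaled"`` (default) for the scale-invariant conic fit with
        post-hoc normalization appropriate for SNV spectra.
    """
    if isinstance(x, Spectrum):
        if E.wavelengths is not None and (
            len(x) != E.n_bands or not np.allclose(x.wavelengths, E.wavelengths)
        ):
            raise BandGridError("spectrum and endmembers are on different band grids")
        xv = x.values
    else:
        xv = np.asarray(x, dtype=float)
        if xv.shape != (E.n_bands,):
            raise BandGridError(
                f"spectrum length {xv.shape} does not match endmember grid ({E.n_bands},)"
            )
    if not E.n_classes < E.n_bands - 1:
        raise IllPosedUnmixingError("need C < m - 1 bands for a determined fit")
    if sum_to_one not in ("constrained", "rescaled"):
        raise ValueError(f"unknown sum_to_one mode {sum_to_one!r}")

    if sum_to_one == "rescaled":
        result = _nnls_rescaled(E.spectra, xv)
        if result is None:
            result = _fcls_simplex(E.spectra, xv)
    else:
        result = _fcls_simplex(E.spectra, xv)
    a, resid = result
    a = np.where((a < 0) & (a > -_ANC_CLAMP), 0.0, a)
    a = a / a.sum()
    return AbundanceVector(a, E.classes, resid)


def tumor_abundance(a: AbundanceVector) -> float:
    """Combined malignant (IC + CIS) fraction of an abundance vector."""
    idx = [i for i, c in enumerate(a.classes) if c in MALIGNANT_CLASSES]
    return float(np.clip(a.values[idx].sum(), 0.0, 1.0))


def unmix_patch(
    patch_block: np.ndarray, E: EndmemberSet, sum_to_one: str = "rescaled"
) -> AbundanceMap:
    """Unmix every pixel of an (H, W, bands) block.

    Deterministic given its inputs; used to build the tumor prediction
    map of a 10x10 ink-mark patch.
    """
    block = np.asarray(patch_block, dtype=float)
    if block.ndim != 3 or block.shape[2] != E.n_bands:
        raise ShapeMismatchError(
            f"patch block {block.shape} incompatible with {E.n_bands}-band endmembers"
        )
    H, W, _ = block.shape
    abundances = np.empty((H, W, E.n_classes))
    residuals = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            av = unmix_spectrum(block[i, j], E, sum_to_one=sum_to_one)
            abundances[i, j] = av.values
            residuals[i, j] = av.residual_norm
    return AbundanceMap(abundances, E.classes, residuals)
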