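"""Natural-isotope-abundance correction of raw mass-isotopomer spectra.

A measured fragment's mass distribution mixes the tracer 13C signal with
naturally occurring heavy isotopes of every atom in the fragment (H, N, O,
S, Si of derivatization groups, and the natural 13C of skeleton carbons
not enriched by the tracer).  The correction matrix K maps the tracer-only
carbon-skeleton MDV to the observable distribution; its column j is the
spectrum of a fragment carrying exactly j tracer carbons.  Correction
solves ``K m ~= raw`` by nonnegative least squares and renormalizes.

Natural abundances are a versioned table below (Rosman & Taylor, IUPAC
1998 representative isotopic compositions, rounded as commonly tabulated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from .mdv import as_mdv

__all__ = [
    "NATURAL_ABUNDANCE",
    "FragmentComposition",
    "CorrectionMatrix",
    "build_correction_matrix",
    "correct_spectrum",
]

#: mass-shift distributions (m+0, m+1, m+2, ...) of natural isotopes, per element
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Si": (0.92223, 0.04685, 0.03092),
    "P": (1.0,),
}


@dataclass(frozen=True)
class FragmentComposition:
    """Elemental composition of a measured fragment.

    ``skeleton_carbons`` counts the carbons that can carry tracer label;
    ``elements`` holds the full atom counts including those carbons.
    """

    label: str
    elements: Mapping[str, int]
    skeleton_carbons: int

    def __post_init__(self):
        object.__setattr__(self, "elements", dict(self.elements))
        if any(n < 0 for n in self.elements.values()):
            raise ValueError("element counts must be nonnegative")
        if self.skeleton_carbons > self.elements.get("C", 0):
            raise ValueError(
                f"fragment {self.label}: skeleton carbons "
                f"({self.skeleton_carbons}) exceed total C "
                f"({self.elements.get('C', 0)})"
            )


@dataclass
class CorrectionMatrix:
    """Maps a skeleton MDV (length ``skeleton_carbons+1``) to the observed
    mass window (length ``window``)."""

    K: np.ndarray
    skeleton_carbons: int
    label: str = ""

    @property
    def window(self) -> int:
        return self.K.shape[0]


def _natural_pattern(element: str, count: int, table: Mapping[str, Sequence[float]]) -> np.ndarray:
    if element not in table:
        raise ValueError(
            f"unknown element {element!r}; supported: {sorted(table)}"
        )
    out = np.array([1.0])
    base = np.asarray(table[element], dtype=float)
    for _ in range(count):
        out = np.convolve(out, base)
    return out


def build_correction_matrix(
    comp: FragmentComposition,
    window: int,
    *,
    natural_abundances: Mapping[str, Sequence[float]] | None = None,
    correct_skeleton_c13: bool = True,
) -> CorrectionMatrix:
    """Construct the correction matrix for one fragment.

    Column ``j`` is the observable mass distribution of a fragment with
    exactly ``j`` tracer-labeled skeleton carbons: a pure ``m+j`` shift
    convolved with the natural-isotope distributions of all non-skeleton
    atoms, and (if ``correct_skeleton_c13``) with natural 13C over the
    remaining ``skeleton_carbons - j`` unlabeled skeleton positions.
    """
    table = dict(NATURAL_ABUNDANCE)
    if natural_abundances:
        table.update({k: tuple(v) for k, v in natural_abundances.items()})
    nskel = comp.skeleton_carbons
    if window < nskel + 1:
        raise ValueError(
            f"window {window} too small for {nskel} skeleton carbons"
        )

    base = np.array([1.0])
    for el, n in comp.elements.items():
        count = n - nskel if el == "C" else n
        base = np.convolve(base, _natural_pattern(el, count, table))

    K = np.zeros((window, nskel + 1))
    for j in range(nskel + 1):
        col = base.copy()
        if correct_skeleton_c13 and nskel - j > 0:
            col = np.convolve(col, _natural_pattern("C", nskel - j, table))
        full = np.zeros(j + col.size)
        full[j:] = col  # tracer carbons shift the whole pattern up by j
        K[:, j] = full[:window] if full.size >= window else np.pad(
            full, (0, window - full.size))
    return CorrectionMatrix(K=K, skeleton_carbons=nskel, label=comp.label)


def correct_spectrum(
    raw: Sequence[float],
    K: CorrectionMatrix,
    *,
    method: str = "nnls",
) -> np.ndarray:
    """Recover the carbon-skeleton MDV from a raw intensity spectrum.

    Solves ``K m ~= raw`` (``method='nnls'`` for nonnegative least squares,
    the default; ``'pinv'`` for the unconstrained pseudo-inverse, useful as
    a diagnostic) and normalizes the solution to sum 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw spectrum must be a 1-D vector")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be nonnegative")
    if not np.any(raw > 0):
        raise ValueError("degenerate spectrum: all intensities are zero")
    if raw.size < K.skeleton_carbons + 1:
        raise ValueError(
            f"spectrum window {raw.size} too small for "
            f"{K.skeleton_carbons} skeleton carbons"
        )
    A = K.K
    if raw.size != A.shape[0]:
        if raw.size < A.shape[0]:
            raw = np.pad(raw, (0, A.shape[0] - raw.size))
        else:
            raise ValueError(
                f"spectrum has {raw.size} channels but the correction matrix "
                f"window is {A.shape[0]}"
            )
    if method == "pinv":
        m = np.linalg.pinv(A) @ raw
    elif method == "nnls":
        m, _ = scipy.optimize.nnls(A, raw)
    else:
        raise ValueError(f"unknown method {method!r}")
    return as_mdv(m)
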