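"""Mass distribution vectors (MDVs) and tracer labeling of carbon sources.

An MDV holds the fractional abundances ``m+0 .. m+n`` of a metabolite
fragment carrying 0..n heavy (13C) carbons; the entries sum to 1.  MDVs are
plain 1-D ``numpy`` arrays throughout the package; this module provides the
validation and convolution primitives everything else builds on.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "as_mdv",
    "validate_mdv",
    "convolve_mdv",
    "unlabeled_mdv",
    "SubstrateLabeling",
]

#: tolerance below which small negative entries are treated as roundoff
_NEG_SLACK = 1e-9


def as_mdv(values: Sequence[float]) -> np.ndarray:
    """Coerce *values* to a float array and normalize it to sum 1."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("an MDV must be a nonempty 1-D vector")
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot normalize an MDV with nonpositive total")
    return arr / total

def validate_mdv(arr: np.ndarray, *, atol: float = 1e-6) -> None:
    """Raise ``ValueError`` unless *arr* is a valid MDV (sum 1, entries >= 0)."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("an MDV must be a nonempty 1-D vector")
    if np.any(arr < -_NEG_SLACK):
        raise ValueError(f"MDV has negative entries: {arr}")
    if abs(arr.sum() - 1.0) > atol:
        raise ValueError(f"MDV entries sum to {arr.sum():.6g}, expected 1")


def convolve_mdv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """MDV of a molecule condensed from two independent precursor fragments.

    The probability of carrying ``k`` heavy carbons in the condensation
    product is the discrete convolution of the precursor MDVs; the result
    has length ``len(a) + len(b) - 1`` and is renormalized to absorb
    floating-point drift.
    """
    out = np.convolve(np.asarray(a, float), np.asarray(b, float))
    s = out.sum()
    if s > 0:
        out /= s
    return out


def unlabeled_mdv(n_atoms: int) -> np.ndarray:
    """MDV of a fully unlabeled fragment with *n_atoms* carbons."""
    out = np.zeros(n_atoms + 1)
    out[0] = 1.0
    return out


def _parse_pattern(pattern, carbons: int) -> tuple[int, ...]:
    """Parse a positional labeling pattern into a 0/1 tuple of length *carbons*.

    Accepts named forms ("U-13C", "1-13C", "2-13C", ..., "unlabeled"),
    digit strings ("100" = first carbon labeled) and 0/1 sequences.
    """
    if isinstance(pattern, str):
        name = pattern.strip()
        low = name.lower()
        if low in ("u-13c", "u13c", "uniform"):
            return (1,) * carbons
        if low in ("unlabeled", "12c", "none"):
            return (0,) * carbons
        if low.endswith("-13c"):
            pos = int(low[:-4])
            if not 1 <= pos <= carbons:
                raise ValueError(f"labeled position {pos} outside 1..{carbons}")
            return tuple(1 if i == pos - 1 else 0 for i in range(carbons))
        if set(name) <= {"0", "1"}:
            bits = tuple(int(c) for c in name)
            if len(bits) != carbons:
                raise ValueError(
                    f"pattern {name!r} has {len(bits)} positions, expected {carbons}"
                )
            return bits
        raise ValueError(f"unrecognized labeling pattern {pattern!r}")
    bits = tuple(int(b) for b in pattern)
    if len(bits) != carbons or any(b not in (0, 1) for b in bits):
        raise ValueError(f"pattern {pattern!r} invalid for {carbons} carbons")
    return bits


class SubstrateLabeling:
    """Positional 13C labeling of the carbon sources.

    Each source metabolite carries a mixture of positional labeling
    patterns with fractions summing to 1, e.g. pyruvate fed as 50%
    [1-13C] plus 50% [U-13C]::

        SubstrateLabeling({"Subs_PYR_EX": [("1-13C", 0.5), ("U-13C", 0.5)]},
                          carbons={"Subs_PYR_EX": 3})

    Unlisted metabolites default to natural (here: zero) labeling, which is
    how e.g. an unlabeled CO2 pool enters condensation reactions.
    """

    def __init__(
        self,
        mixtures: Mapping[str, Iterable[tuple[object, float]]],
        carbons: Mapping[str, int],
    ):
        self._mix: dict[str, list[tuple[tuple[int, ...], float]]] = {}
        for met, comps in mixtures.items():
            if met not in carbons:
                raise ValueError(f"carbon count for substrate {met!r} unknown")
            nc = carbons[met]
            parsed = [(_parse_pattern(p, nc), float(f)) for p, f in comps]
            total = sum(f for _, f in parsed)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"labeling fractions of {met!r} sum to {total:.6g}, expected 1"
                )
            self._mix[met] = parsed
        self._carbons = dict(carbons)

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(self._mix)

    def has(self, metabolite: str) -> bool:
        return metabolite in self._mix

    def emu_mdv(self, metabolite: str, atoms: Sequence[int]) -> np.ndarray:
        """MDV of the EMU of *metabolite* restricted to 1-based *atoms*.

        Patterns are deterministic positional labelings, so each mixture
        component contributes a point mass at its heavy-atom count within
        the selected positions.
        """
        atoms = tuple(atoms)
        out = np.zeros(len(atoms) + 1)
        if metabolite not in self._mix:
            out[0] = 1.0
            return out
        for bits, frac in self._mix[metabolite]:
            k = sum(bits[a - 1] for a in atoms)
            out[k] += frac
        return out
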