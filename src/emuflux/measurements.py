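"""Measured MS fragments and labeling measurement sets.

A *fragment* names what the mass spectrometer sees: one EMU, or a
convolution of EMUs for fragments assembled from several precursor
skeletons (e.g. valine carried by two pyruvate units).  Fragment
declarations live in ``MSReac.csv`` with rows like::

    Fragment,EMU
    Asp,OAA:1-4
    Val,PYR:1-3 + PYR:2-3

Measured spectra arrive as a series of ``Abundance_list*.csv`` files (one
per time point for a nonstationary experiment, one per replicate or a
single file for a stationary one), each with a ``Fragment`` column and
``m0, m1, ...`` intensity columns.  ``Components.csv`` gives the
elemental composition used for natural-abundance correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correction import FragmentComposition, build_correction_matrix, correct_spectrum
from .emu import EMU
from .mdv import as_mdv, convolve_mdv

__all__ = [
    "FragmentSpec",
    "MeasurementSet",
    "parse_fragment_spec",
    "load_fragments",
    "load_components",
    "load_measurements",
    "fragment_mdv",
    "correct_measurements",
]


@dataclass(frozen=True)
class FragmentSpec:
    """A measured fragment: label plus the EMU(s) whose MDVs convolve into it."""

    label: str
    terms: tuple[EMU, ...]

    @property
    def carbons(self) -> int:
        return sum(e.size for e in self.terms)

    @property
    def width(self) -> int:
        return self.carbons + 1


def _parse_atoms(text: str) -> tuple[int, ...]:
    text = text.strip()
    m = re.fullmatch(r"(\d+)-(\d+)", text)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ValueError(f"bad atom range {text!r}")
        return tuple(range(lo, hi + 1))
    return tuple(int(p) for p in text.split(","))


def parse_fragment_spec(label: str, spec: str) -> FragmentSpec:
    """Parse ``"OAA:1-4"`` or ``"PYR:1-3 + PYR:2-3"`` into a FragmentSpec."""
    terms = []
    for part in spec.split("+"):
        part = part.strip()
        if ":" not in part:
            raise ValueError(f"fragment term {part!r} lacks ':atoms'")
        met, atoms = part.split(":", 1)
        terms.append(EMU(met.strip(), _parse_atoms(atoms)))
    if not terms:
        raise ValueError(f"empty fragment spec for {label!r}")
    return FragmentSpec(label=label, terms=tuple(terms))


def load_fragments(path) -> list[FragmentSpec]:
    """Read MSReac.csv (columns ``Fragment``, ``EMU``)."""
    df = pd.read_csv(path, skipinitialspace=True)
    return [
        parse_fragment_spec(str(r["Fragment"]).strip(), str(r["EMU"]))
        for _, r in df.iterrows()
    ]


def load_components(path) -> dict[str, FragmentComposition]:
    """Read Components.csv: ``Fragment``, element columns, ``Skeleton_C``."""
    df = pd.read_csv(path, skipinitialspace=True)
    out = {}
    for _, r in df.iterrows():
        label = str(r["Fragment"]).strip()
        elements = {
            c: int(r[c]) for c in df.columns
            if c not in ("Fragment", "Skeleton_C") and not pd.isna(r[c]) and int(r[c]) > 0
        }
        out[label] = FragmentComposition(
            label=label, elements=elements, skeleton_carbons=int(r["Skeleton_C"])
        )
    return out


def fragment_mdv(solved: Mapping[EMU, np.ndarray], frag: FragmentSpec) -> np.ndarray:
    """Simulated MDV of a fragment from per-EMU MDVs (convolving multi-EMU
    fragments)."""
    mdv = solved[frag.terms[0]]
    for emu in frag.terms[1:]:
        mdv = convolve_mdv(mdv, solved[emu])
    return mdv


@dataclass
class MeasurementSet:
    """Per-fragment spectra across sampling points.

    ``times`` is ``None`` for a stationary experiment (the ``n_samples``
    axis then holds replicates); otherwise it lists the sampling times of
    a labeling time course.  ``spectra[label]`` has shape
    ``(n_samples, width)``.  ``sd[label]`` holds the per-channel
    measurement standard deviations (the square roots of the diagonal
    measurement covariance).
    """

    fragments: dict[str, FragmentSpec]
    spectra: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    times: np.ndarray | None = None
    compositions: dict[str, FragmentComposition] | None = None
    corrected: bool = False

    def __post_init__(self):
        ns = {a.shape[0] for a in self.spectra.values()}
        if len(ns) > 1:
            raise ValueError(f"fragments have inconsistent sample counts: {ns}")
        if self.times is not None and self.spectra:
            if self.n_samples != len(self.times):
                raise ValueError(
                    f"{self.n_samples} spectra per fragment but "
                    f"{len(self.times)} sampling times"
                )

    @property
    def labels(self) -> list[str]:
        return list(self.fragments)

    @property
    def n_samples(self) -> int:
        return next(iter(self.spectra.values())).shape[0] if self.spectra else 0

    @property
    def n_metabolites(self) -> int:
        return len(self.fragments)

    def n_independent(self) -> int:
        """Independent data points: per fitted MDV, length minus one (the
        normalization constraint removes one degree per vector)."""
        return sum(
            (arr.shape[1] - 1) * arr.shape[0] for arr in self.spectra.values()
        )


def load_measurements(
    abundance_files: Sequence,
    components=None,
    time_course=None,
    *,
    fragments: Sequence[FragmentSpec] | None = None,
    sd: float = 0.01,
) -> MeasurementSet:
    """Assemble a :class:`MeasurementSet` from Abundance_list.csv files.

    *components* is a Components.csv path (or parsed dict); required later
    for natural-abundance correction — loading fails fast if a measured
    fragment has no composition entry.  *time_course* is a Time_course.csv
    path or a sequence of times; omit it for a stationary experiment.
    *sd* is the per-channel measurement standard deviation applied
    uniformly (Abundance files carry no uncertainty columns).
    """
    if isinstance(components, (str, Path)):
        components = load_components(components)
    times = None
    if time_course is not None:
        if isinstance(time_course, (str, Path)):
            tdf = pd.read_csv(time_course, skipinitialspace=True)
            times = np.asarray(tdf[tdf.columns[0]], dtype=float)
        else:
            times = np.asarray(time_course, dtype=float)
        if len(abundance_files) != len(times):
            raise ValueError(
                f"{len(abundance_files)} abundance files but "
                f"{len(times)} sampling times"
            )

    per_frag: dict[str, list[np.ndarray]] = {}
    for f in abundance_files:
        df = pd.read_csv(f, skipinitialspace=True)
        cols = [c for c in df.columns if c != "Fragment"]
        for _, row in df.iterrows():
            label = str(row["Fragment"]).strip()
            vec = row[cols].to_numpy(dtype=float)
            vec = vec[~np.isnan(vec)]
            if not np.any(vec > 0):
                raise ValueError(
                    f"degenerate spectrum: fragment {label!r} in {f} is all zero"
                )
            per_frag.setdefault(label, []).append(vec)

    if components is not None:
        missing = set(per_frag) - set(components)
        if missing:
            raise ValueError(
                f"fragments {sorted(missing)} missing from Components.csv; "
                f"natural-abundance correction impossible"
            )

    frag_specs: dict[str, FragmentSpec] = {}
    if fragments is not None:
        frag_specs = {fs.label: fs for fs in fragments if fs.label in per_frag}

    spectra, sds = {}, {}
    for label, vecs in per_frag.items():
        widths = {v.size for v in vecs}
        if len(widths) > 1:
            raise ValueError(f"fragment {label!r} spectra have varying widths {widths}")
        spectra[label] = np.vstack(vecs)
        sds[label] = np.full_like(spectra[label], sd)
        if label not in frag_specs:
            frag_specs[label] = FragmentSpec(label, ())  # spec unknown yet

    # keep declared fragment order where provided
    if fragments is not None:
        order = [fs.label for fs in fragments if fs.label in spectra]
        order += [l for l in spectra if l not in order]
        frag_specs = {l: frag_specs[l] for l in order}
        spectra = {l: spectra[l] for l in order}
        sds = {l: sds[l] for l in order}

    return MeasurementSet(
        fragments=frag_specs, spectra=spectra, sd=sds, times=times,
        compositions=components,
    )


def correct_measurements(
    mset: MeasurementSet,
    *,
    correct_skeleton_c13: bool = True,
    normalize_only: bool = False,
) -> MeasurementSet:
    """Convert raw spectra into carbon-skeleton MDVs.

    With ``normalize_only`` the spectra are just normalized to sum 1
    (appropriate when the data are already skeleton fractions, as for the
    synthetic bundles); otherwise each fragment's correction matrix is
    built from its composition and inverted per spectrum.
    """
    new_spectra = {}
    for label, arr in mset.spectra.items():
        if normalize_only:
            new_spectra[label] = np.vstack([as_mdv(row) for row in arr])
            continue
        if mset.compositions is None or label not in mset.compositions:
            raise ValueError(f"no composition for fragment {label!r}")
        K = build_correction_matrix(
            mset.compositions[label], window=arr.shape[1],
            correct_skeleton_c13=correct_skeleton_c13,
        )
        new_spectra[label] = np.vstack([correct_spectrum(row, K) for row in arr])
    out = replace(mset, spectra=new_spectra, corrected=True)
    # corrected vectors may be shorter than the raw window
    out.sd = {
        l: np.full_like(new_spectra[l], mset.sd[l].flat[0]) for l in new_spectra
    }
    return out
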