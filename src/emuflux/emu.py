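"""Elementary metabolite unit (EMU) decomposition of a carbon-transition network.

An EMU is a specific subset of one metabolite's carbon atoms.  Labeling of
a measured fragment depends only on the EMUs that feed it, so the full
isotopomer problem decomposes into a cascade of linear systems, one per
EMU size: for the unknown EMUs ``Z_s`` of size ``s``,

    A_s(v) Z_s = B_s(v) Y_s

where ``Y_s`` collects source EMUs (substrate labeling) and convolutions
of already-solved smaller EMUs (condensation reactions), ``A_s`` carries
total consumption on the diagonal and same-size transfer fluxes off it,
and ``B_s`` the inflows from ``Y_s`` (with a minus sign).

Symmetric metabolites (``Sym_`` prefix) are handled by splitting every
atom mapping that touches them into forward and fully reversed variants
of half weight, the standard treatment of rotational scrambling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import product as iproduct
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mdv import SubstrateLabeling, convolve_mdv
from .model import MetabolicModel, Reaction

__all__ = [
    "EMU",
    "EMUReaction",
    "EMUNetwork",
    "TracingError",
    "trace_emu",
    "build_emu_network",
    "assemble_balance_matrices",
    "source_mdv",
]


class TracingError(ValueError):
    """Atom tracing failed (missing atom map, malformed target, ...)."""


@dataclass(frozen=True, order=True)
class EMU:
    """One metabolite's atom subset, with 1-based positions."""

    metabolite: str
    atoms: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))
        if not self.atoms or len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"EMU atoms must be a nonempty set, got {self.atoms}")
        if min(self.atoms) < 1:
            raise ValueError("EMU atom positions are 1-based")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        return f"{self.metabolite}{{{','.join(map(str, self.atoms))}}}"


@dataclass(frozen=True)
class EMUReaction:
    """One labeling inflow: product EMU fed by 1 precursor (transfer) or 2
    (condensation; the product MDV contribution is their convolution)."""

    product_emu: EMU
    precursor_emus: tuple[EMU, ...]
    flux_id: str
    weight: float = 1.0

    def __post_init__(self):
        if len(self.precursor_emus) not in (1, 2):
            raise ValueError("EMU reactions have 1 or 2 precursors")
        if sum(e.size for e in self.precursor_emus) != self.product_emu.size:
            raise ValueError(
                f"precursor sizes of {self.flux_id} do not add up to the "
                f"product size for {self.product_emu}"
            )


def _is_source_met(model: MetabolicModel, name: str) -> bool:
    role = model.role(name)
    return role.is_source or role.is_unbalanced


def _variant_strings(model, species, strings):
    """All orientation variants (string per species, weight) after scrambling
    each symmetric species independently."""
    sym_idx = [i for i, m in enumerate(species) if model.role(m).is_symmetric]
    if not sym_idx:
        yield tuple(strings), 1.0
        return
    w = 0.5 ** len(sym_idx)
    for flips in iproduct((False, True), repeat=len(sym_idx)):
        variant = list(strings)
        for flip, i in zip(flips, sym_idx):
            if flip:
                variant[i] = variant[i][::-1]
        yield tuple(variant), w


def trace_emu(model: MetabolicModel, target: EMU) -> list[EMUReaction]:
    """Map *target*'s atoms back through every producing reaction.

    Returns the EMU reactions feeding *target*, with symmetric-metabolite
    scrambling expanded into weighted alternatives (identical alternatives
    merged; weights over one producing reaction occurrence sum to 1).
    """
    role = model.role(target.metabolite)
    if max(target.atoms) > role.carbons:
        raise TracingError(
            f"EMU {target} exceeds the {role.carbons} carbons of {target.metabolite}"
        )
    producers = model.producing_reactions(target.metabolite)
    if not producers:
        raise TracingError(f"no reaction produces {target.metabolite}")

    merged: dict[tuple, float] = defaultdict(float)
    order: list[tuple] = []
    for rxn in producers:
        if rxn.atom_map is None:
            raise TracingError(
                f"reaction {rxn.flux_id} produces {target.metabolite} "
                f"without an atom map"
            )
        sub_names = [m for m, _ in rxn.substrates]
        prod_names = [m for m, _ in rxn.products]
        species = sub_names + prod_names
        strings = list(rxn.atom_map.reactant_strings) + list(rxn.atom_map.product_strings)
        n_sub = len(sub_names)
        occurrences = [
            k for k, m in enumerate(prod_names) if m == target.metabolite
        ]
        for occ in occurrences:
            for variant, w in _variant_strings(model, species, strings):
                rstrings = variant[:n_sub]
                pstring = variant[n_sub + occ]
                letters = [pstring[a - 1] for a in target.atoms]
                by_sub: dict[int, list[int]] = defaultdict(list)
                for letter in letters:
                    for si, s in enumerate(rstrings):
                        pos = s.find(letter)
                        if pos >= 0:
                            by_sub[si].append(pos + 1)
                            break
                    else:  # pragma: no cover - excluded by AtomMap balance check
                        raise TracingError(
                            f"atom {letter!r} of {target} not found on the "
                            f"substrate side of {rxn.flux_id}"
                        )
                precursors = tuple(sorted(
                    EMU(sub_names[si], tuple(pos)) for si, pos in by_sub.items()
                ))
                if len(precursors) > 2:
                    raise TracingError(
                        f"{target} draws atoms from {len(precursors)} precursors "
                        f"in {rxn.flux_id}; at most 2 supported"
                    )
                key = (rxn.flux_id, precursors)
                if key not in merged:
                    order.append(key)
                merged[key] += w

    return [
        EMUReaction(target, precursors, flux_id, weight)
        for (flux_id, precursors), weight in ((k, merged[k]) for k in order)
    ]


class EMUNetwork:
    """Minimal size-stratified EMU cascade reaching a set of target EMUs."""

    def __init__(
        self,
        model: MetabolicModel,
        targets: Sequence[EMU],
        reactions: Mapping[EMU, Sequence[EMUReaction]],
        sources: Iterable[EMU],
    ):
        self.model = model
        self.targets = list(targets)
        self.reactions_by_product = {k: list(v) for k, v in reactions.items()}
        self.sources = set(sources)
        by_size: dict[int, list[EMU]] = defaultdict(list)
        for emu in self.reactions_by_product:
            by_size[emu.size].append(emu)
        self.unknowns_by_size = {s: sorted(v) for s, v in sorted(by_size.items())}

    @property
    def sizes(self) -> list[int]:
        return sorted(self.unknowns_by_size)

    @property
    def unknowns(self) -> list[EMU]:
        return [e for s in self.sizes for e in self.unknowns_by_size[s]]

    @property
    def n_unknowns(self) -> int:
        return sum(len(v) for v in self.unknowns_by_size.values())

    def consumption(self, v) -> dict[str, float]:
        """Total consuming flux per traced metabolite under flux values *v*."""
        if not isinstance(v, Mapping):
            v = dict(zip(self.model.flux_ids, np.asarray(v, float)))
        mets = {e.metabolite for e in self.reactions_by_product}
        return {m: self.model.consumption(m, v) for m in mets}


def build_emu_network(model: MetabolicModel, targets: Sequence[EMU]) -> EMUNetwork:
    """Breadth-first closure from *targets* down to substrate/unbalanced sources."""
    reactions: dict[EMU, list[EMUReaction]] = {}
    sources: set[EMU] = set()
    queue = [t for t in targets]
    seen: set[EMU] = set()
    while queue:
        emu = queue.pop(0)
        if emu in seen:
            continue
        seen.add(emu)
        if _is_source_met(model, emu.metabolite):
            sources.add(emu)
            continue
        rxns = trace_emu(model, emu)
        reactions[emu] = rxns
        for r in rxns:
            queue.extend(r.precursor_emus)
    return EMUNetwork(model, targets, reactions, sources)


def source_mdv(labeling: SubstrateLabeling, emu: EMU) -> np.ndarray:
    """MDV of a source EMU from the substrate labeling (unlabeled if unlisted,
    which is how an ``Ind_`` donor pool such as CO2 defaults)."""
    return labeling.emu_mdv(emu.metabolite, emu.atoms)


def assemble_balance_matrices(
    net: EMUNetwork,
    size: int,
    v,
    solved: Mapping[EMU, np.ndarray],
):
    """Build ``A_s``, ``B_s`` and the known-input matrix ``Y_s`` for one size.

    *solved* must hold MDVs of every source EMU and every unknown EMU of
    size < *size*.  Returns ``(A, B, Y, unknowns, y_keys)`` where ``y_keys``
    names each row of ``Y`` as a tuple of the EMUs convolved into it.

    Sign conventions: ``A`` has minus total consumption on the diagonal and
    inflow fluxes from same-size unknowns off it; ``B[i, j]`` is minus the
    flux into unknown ``i`` from known row ``j``; the steady state solves
    ``A Z = B Y``.
    """
    if not isinstance(v, Mapping):
        v = dict(zip(net.model.flux_ids, np.asarray(v, float)))
    unknowns = net.unknowns_by_size.get(size, [])
    idx = {e: i for i, e in enumerate(unknowns)}
    consumption = net.consumption(v)

    y_keys: list[tuple[EMU, ...]] = []
    y_index: dict[tuple[EMU, ...], int] = {}
    entries_B: list[tuple[int, int, float]] = []
    A = np.zeros((len(unknowns), len(unknowns)))

    def y_row(key: tuple[EMU, ...]) -> int:
        if key not in y_index:
            y_index[key] = len(y_keys)
            y_keys.append(key)
        return y_index[key]

    for emu in unknowns:
        i = idx[emu]
        cons = consumption[emu.metabolite]
        if cons <= 0:
            raise ValueError(
                f"metabolite {emu.metabolite!r} has zero total consumption; "
                f"the size-{size} EMU balance is singular"
            )
        A[i, i] -= cons
        for er in net.reactions_by_product[emu]:
            w = v[er.flux_id] * er.weight
            pres = er.precursor_emus
            if len(pres) == 1 and pres[0] in idx:
                A[i, idx[pres[0]]] += w
            else:
                entries_B.append((i, y_row(pres), -w))

    width = size + 1
    Y = np.zeros((len(y_keys), width))
    for j, key in enumerate(y_keys):
        mdv = solved[key[0]]
        for extra in key[1:]:
            mdv = convolve_mdv(mdv, solved[extra])
        if mdv.shape[0] != width:
            raise ValueError(f"known input {key} has wrong MDV length")
        Y[j] = mdv

    B = np.zeros((len(unknowns), max(len(y_keys), 0)))
    for i, j, val in entries_B:
        B[i, j] += val
    return A, B, Y, unknowns, y_keys
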