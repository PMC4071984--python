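"""Metabolic network configuration: reactions, atom maps, stoichiometry.

The model is declared in a worksheet (CSV or XLSX) with columns
``FluxID``, ``Rxns``, ``Net flux`` and ``Carbon_transitions``::

    R3, ACCOA + OAA -> IsoCit, 0, ab + cdef -> fedbac

Metabolite roles are carried by naming conventions, the sole
role-declaration mechanism:

* ``Subs_`` prefix — extracellular carbon source; excluded from mass
  balance, its labeling is an input.
* ``Ind_`` prefix — unbalanced pool (e.g. ``Ind_CO2``); excluded from mass
  balance, treated as an unlabeled source when it donates carbon.
* ``Sym_`` prefix — rotationally symmetric molecule (e.g. succinate);
  atom maps touching it are scrambled half-and-half.
* ``[...]`` brackets on a product — sink pseudo-metabolite (biomass drain),
  never balanced or traced; by convention suffixed ``_B``.
* ``_EX`` suffix — exo-metabolite.

The ``Net flux`` column tags reversible pairs: rows sharing the same
nonzero tag are the forward/backward directions of one reversible
reaction; 0 marks an irreversible step.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomMap",
    "Reaction",
    "MetaboliteRole",
    "MetabolicModel",
    "ConfigError",
    "parse_config",
    "build_stoichiometry",
    "serialize_config",
]


class ConfigError(ValueError):
    """Invalid model configuration (atom imbalance, duplicate ids, ...)."""


_ARROWS = ("→", "->", "=")


@dataclass(frozen=True)
class AtomMap:
    """Carbon transitions of one reaction, as parallel letter strings.

    ``reactant_strings[i]`` assigns one lowercase letter per carbon of the
    i-th substrate; the same letters reappear in ``product_strings`` at the
    positions the atoms move to (e.g. ``ab + cdef -> fedbac``).
    """

    reactant_strings: tuple[str, ...]
    product_strings: tuple[str, ...]

    def __post_init__(self):
        left = Counter("".join(self.reactant_strings))
        right = Counter("".join(self.product_strings))
        if len(left) != sum(left.values()) or len(right) != sum(right.values()):
            raise ConfigError(
                f"atom letters repeat within one side of map "
                f"{self.reactant_strings} -> {self.product_strings}"
            )
        if left != right:
            raise ConfigError(
                f"atom letters unbalanced between sides of map "
                f"{self.reactant_strings} -> {self.product_strings}"
            )


@dataclass(frozen=True)
class Reaction:
    flux_id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    atom_map: AtomMap | None
    pair_tag: int = 0
    kind: str = "internal"  # internal | substrate_input | biomass_drain | excretion

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.substrates) + tuple(m for m, _ in self.products)


@dataclass(frozen=True)
class MetaboliteRole:
    name: str
    carbons: int = 0
    is_symmetric: bool = False
    is_unbalanced: bool = False
    is_source: bool = False
    is_sink: bool = False

    @property
    def balanced(self) -> bool:
        return not (self.is_unbalanced or self.is_source or self.is_sink)


@dataclass
class MetabolicModel:
    """Parsed network: reactions, metabolite roles, stoichiometry, constraints."""

    reactions: list[Reaction]
    metabolites: dict[str, MetaboliteRole]
    fixed_fluxes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.S, self.balanced_metabolites = build_stoichiometry(self)

    @property
    def flux_ids(self) -> list[str]:
        return [r.flux_id for r in self.reactions]

    def reaction(self, flux_id: str) -> Reaction:
        for r in self.reactions:
            if r.flux_id == flux_id:
                return r
        raise KeyError(flux_id)

    def flux_index(self, flux_id: str) -> int:
        try:
            return self.flux_ids.index(flux_id)
        except ValueError:
            raise KeyError(flux_id) from None

    def role(self, name: str) -> MetaboliteRole:
        return self.metabolites[name]

    def producing_reactions(self, metabolite: str) -> list[Reaction]:
        return [r for r in self.reactions if any(m == metabolite for m, _ in r.products)]

    def consuming_reactions(self, metabolite: str) -> list[Reaction]:
        return [r for r in self.reactions if any(m == metabolite for m, _ in r.substrates)]

    def consumption(self, metabolite: str, v: Mapping[str, float] | np.ndarray) -> float:
        """Total flux draining *metabolite* under flux values *v*."""
        if not isinstance(v, Mapping):
            v = dict(zip(self.flux_ids, np.asarray(v, float)))
        return sum(
            coef * v[r.flux_id]
            for r in self.reactions
            for m, coef in r.substrates
            if m == metabolite
        )

    def set_fixed_fluxes(self, fixed: Mapping[str, float]) -> None:
        unknown = set(fixed) - set(self.flux_ids)
        if unknown:
            raise ConfigError(f"fixed fluxes reference unknown reactions: {sorted(unknown)}")
        self.fixed_fluxes = dict(fixed)


def _strip(name: str) -> str:
    return name.strip()


def _split_side(side: str) -> list[tuple[str, float]]:
    out = []
    for term in side.split("+"):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(\d+(?:\.\d+)?)\s+(.+)$", term)
        if m:
            out.append((_strip(m.group(2)), float(m.group(1))))
        else:
            out.append((term, 1.0))
    return out


def _split_arrow(text: str, what: str, flux_id: str) -> tuple[str, str]:
    for arrow in _ARROWS:
        if arrow in text:
            left, right = text.split(arrow, 1)
            return left, right
    raise ConfigError(f"{what} of {flux_id} has no arrow ('->'): {text!r}")


def _role_from_name(name: str, carbons: int) -> MetaboliteRole:
    sink = name.startswith("[") and name.endswith("]")
    core = name[1:-1] if sink else name
    return MetaboliteRole(
        name=name,
        carbons=carbons,
        is_symmetric=core.startswith("Sym_"),
        is_unbalanced=core.startswith("Ind_"),
        is_source=core.startswith("Subs_"),
        is_sink=sink,
    )


def _classify(reaction_kindless: Reaction, roles: Mapping[str, MetaboliteRole]) -> str:
    if any(roles[m].is_sink for m, _ in reaction_kindless.products):
        return "biomass_drain"
    if any(roles[m].is_source for m, _ in reaction_kindless.substrates):
        return "substrate_input"
    if any(
        m.endswith("_EX") and not roles[m].is_source
        for m, _ in reaction_kindless.products
    ):
        return "excretion"
    return "internal"


def parse_config(source) -> MetabolicModel:
    """Parse a model configuration worksheet into a :class:`MetabolicModel`.

    *source* may be a path to a ``.csv``/``.xlsx`` file, a file-like object,
    a CSV string, or a :class:`pandas.DataFrame` with columns ``FluxID``,
    ``Rxns``, optionally ``Net flux``, and ``Carbon_transitions``.
    """
    df = _read_worksheet(source)

    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    carbons: dict[str, int] = {}
    carbon_origin: dict[str, str] = {}
    raw: list[tuple[str, list, list, AtomMap | None, int]] = []

    for _, row in df.iterrows():
        flux_id = str(row["FluxID"]).strip()
        if not flux_id or flux_id.lower() == "nan":
            continue
        if flux_id in seen_ids:
            raise ConfigError(f"duplicate FluxID {flux_id!r}")
        seen_ids.add(flux_id)

        left, right = _split_arrow(str(row["Rxns"]), "reaction", flux_id)
        subs = _split_side(left)
        prods = _split_side(right)
        if not subs or not prods:
            raise ConfigError(f"reaction {flux_id} lacks substrates or products")

        tag_val = row.get("Net flux", 0)
        pair_tag = 0 if pd.isna(tag_val) else int(float(tag_val))

        trans = row.get("Carbon_transitions", "")
        trans = "" if pd.isna(trans) else str(trans).strip()
        atom_map = None
        if trans:
            tleft, tright = _split_arrow(trans, "carbon transitions", flux_id)
            rstr = tuple(s.strip() for s in tleft.split("+") if s.strip())
            pstr = tuple(s.strip() for s in tright.split("+") if s.strip())
            for s in rstr + pstr:
                if not re.fullmatch(r"[a-z]+", s):
                    raise ConfigError(
                        f"atom string {s!r} of {flux_id} is not contiguous lowercase letters"
                    )
            try:
                atom_map = AtomMap(rstr, pstr)
            except ConfigError as e:
                raise ConfigError(f"reaction {flux_id}: {e}") from None
            # carbon counts per species, checked for cross-reaction consistency
            mapped = [m for m, _ in subs] + [m for m, _ in prods]
            strings = list(rstr) + list(pstr)
            if len(mapped) != len(strings):
                raise ConfigError(
                    f"reaction {flux_id}: {len(mapped)} species but "
                    f"{len(strings)} atom strings"
                )
            for met, s in zip(mapped, strings):
                if met in carbons and carbons[met] != len(s):
                    raise ConfigError(
                        f"metabolite {met!r} has {len(s)} carbons in {flux_id} "
                        f"but {carbons[met]} in {carbon_origin[met]}"
                    )
                carbons.setdefault(met, len(s))
                carbon_origin.setdefault(met, flux_id)
        raw.append((flux_id, subs, prods, atom_map, pair_tag))

    roles = {}
    for flux_id, subs, prods, _, _ in raw:
        for met, _ in subs + prods:
            if met not in roles:
                roles[met] = _role_from_name(met, carbons.get(met, 0))

    for flux_id, subs, prods, atom_map, pair_tag in raw:
        rxn = Reaction(flux_id, tuple(subs), tuple(prods), atom_map, pair_tag)
        reactions.append(
            Reaction(flux_id, tuple(subs), tuple(prods), atom_map, pair_tag,
                     kind=_classify(rxn, roles))
        )

    return MetabolicModel(reactions=reactions, metabolites=roles)


def _read_worksheet(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, (str, Path)) and str(source).lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(source)
    elif isinstance(source, str) and "\n" in source:
        df = pd.read_csv(io.StringIO(source), skipinitialspace=True)
    else:
        df = pd.read_csv(source, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    required = {"FluxID", "Rxns"}
    if not required <= set(df.columns):
        raise ConfigError(f"worksheet must have columns {sorted(required)}; got {list(df.columns)}")
    if "Carbon_transitions" not in df.columns:
        df["Carbon_transitions"] = ""
    return df


def build_stoichiometry(model: MetabolicModel) -> tuple[np.ndarray, list[str]]:
    """Stoichiometric matrix over balanced metabolites (rows) × reactions (cols).

    Source (``Subs_``), unbalanced (``Ind_``) and sink metabolites are
    excluded from the rows, so ``S v = 0`` expresses steady state of the
    intracellular pools only.  Metabolites with only producers or only
    consumers get a (non-fatal) dead-end warning.
    """
    import warnings

    balanced = [name for name, role in model.metabolites.items() if role.balanced]
    balanced.sort(key=lambda n: _first_mention(model, n))
    index = {m: i for i, m in enumerate(balanced)}
    S = np.zeros((len(balanced), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for m, coef in rxn.substrates:
            if m in index:
                S[index[m], j] -= coef
        for m, coef in rxn.products:
            if m in index:
                S[index[m], j] += coef
    for m in balanced:
        row = S[index[m]]
        if not (np.any(row > 0) and np.any(row < 0)):
            warnings.warn(f"metabolite {m!r} is a dead end (only produced or only consumed)")
    return S, balanced


def _first_mention(model: MetabolicModel, name: str) -> int:
    for i, r in enumerate(model.reactions):
        if name in r.metabolites:
            return i
    return len(model.reactions)


def serialize_config(model: MetabolicModel) -> pd.DataFrame:
    """Emit the worksheet representation back (inverse of :func:`parse_config`)."""
    rows = []
    for r in model.reactions:
        def side(terms):
            return " + ".join(
                (f"{int(c)} {m}" if c != 1 else m) for m, c in terms
            )
        trans = ""
        if r.atom_map is not None:
            trans = (" + ".join(r.atom_map.reactant_strings)
                     + " -> " + " + ".join(r.atom_map.product_strings))
        rows.append({
            "FluxID": r.flux_id,
            "Rxns": side(r.substrates) + " -> " + side(r.products),
            "Net flux": r.pair_tag,
            "Carbon_transitions": trans,
        })
    return pd.DataFrame(rows, columns=["FluxID", "Rxns", "Net flux", "Carbon_transitions"])
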