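"""SRM method construction for NAPE species.

Positive-mode collision-induced dissociation of a NAPE precursor cleaves the
C-O bonds on either side of the phosphate, yielding two product ions that
carry the N-acyl chain only:

* F1 — the protonated N-acyl-phosphoethanolamine (neutral
  ``C_(n+2) H_(2n-2dn+6) N O5 P``), and
* F2 — F1 after a phosphate-side neutral loss: H3PO4 by default (a
  dehydrated N-acylethanolamine-type ion) or HPO3 (the protonated
  N-acylethanolamine).

Because both products depend only on the N-acyl chain, monitoring the pair
resolves isobaric structural isomers (same precursor composition, different
N-acyl) that no mass resolution can separate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lipid_model import (
    H3PO4,
    HPO3,
    AnnotationLevel,
    ElementalComposition,
    FattyAcyl,
    NapeSpecies,
    composition,
    get_adduct,
    ion_mz,
    n_acyl_increment,
    parse_name,
)

__all__ = [
    "FragmentKind",
    "NeutralLoss",
    "Transition",
    "MethodTable",
    "IsobarGroup",
    "SchedulingStats",
    "enumerate_species",
    "fragment_ions",
    "build_method",
    "find_isobars",
    "scheduling_stats",
    "write_transition_list",
    "read_transition_list",
]

# Phosphoethanolamine HO-PO(OH)-O-CH2CH2-NH2, the headgroup core of F1.
_PHOSPHOETHANOLAMINE = ElementalComposition(C=2, H=8, N=1, O=4, P=1)


class FragmentKind(str, Enum):
    PHOSPHO_NAE = "phospho_nae"
    NAE_LIKE = "nae_like"


class NeutralLoss(str, Enum):
    NONE = "none"
    H3PO4 = "H3PO4"
    HPO3 = "HPO3"

    @property
    def composition(self) -> ElementalComposition:
        if self is NeutralLoss.H3PO4:
            return H3PO4
        if self is NeutralLoss.HPO3:
            return HPO3
        return ElementalComposition()


class Role(str, Enum):
    QUANTIFIER = "quantifier"
    QUALIFIER = "qualifier"


@dataclass(frozen=True)
class Transition:
    """One scheduled precursor -> product pair for a species."""

    species: NapeSpecies
    precursor_mz: float
    precursor_adduct: str
    product_mz: float
    product_kind: FragmentKind
    role: Role
    collision_energy: float
    polarity: str
    rt_center: float  # minutes
    rt_window: float  # minutes, full width

    def __post_init__(self) -> None:
        if self.product_mz >= self.precursor_mz:
            raise ValueError("product m/z must be below precursor m/z")
        if self.rt_window <= 0:
            raise ValueError("RT window must be positive")

    @property
    def transition_id(self) -> str:
        tag = "F1" if self.product_kind is FragmentKind.PHOSPHO_NAE else "F2"
        return f"{self.species.name}|{tag}"

    @property
    def rt_start(self) -> float:
        return self.rt_center - self.rt_window / 2

    @property
    def rt_end(self) -> float:
        return self.rt_center + self.rt_window / 2


@dataclass
class MethodTable:
    """The scheduled transition set: exactly two transitions per species."""

    transitions: list[Transition]
    q1_window: float = 2.0
    q3_window: float = 2.0
    cycle_time_s: float = 1.0

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        quantifiers: dict[str, int] = {}
        for t in self.transitions:
            counts[t.species.name] = counts.get(t.species.name, 0) + 1
            if t.role is Role.QUANTIFIER:
                quantifiers[t.species.name] = quantifiers.get(t.species.name, 0) + 1
        bad = {n: c for n, c in counts.items() if c != 2}
        if bad:
            raise ValueError(f"each species must contribute exactly 2 transitions: {bad}")
        bad_q = {n: c for n, c in quantifiers.items() if c != 1}
        if bad_q or set(quantifiers) != set(counts):
            raise ValueError("each species must have exactly one quantifier transition")

    def species_names(self) -> list[str]:
        seen: list[str] = []
        for t in self.transitions:
            if t.species.name not in seen:
                seen.append(t.species.name)
        return seen

    def transitions_for(self, name: str) -> list[Transition]:
        return [t for t in self.transitions if t.species.name == name]

    def quantifier(self, name: str) -> Transition:
        return next(t for t in self.transitions_for(name) if t.role is Role.QUANTIFIER)

    def qualifier(self, name: str) -> Transition:
        return next(t for t in self.transitions_for(name) if t.role is Role.QUALIFIER)

    def by_id(self, transition_id: str) -> Transition:
        for t in self.transitions:
            if t.transition_id == transition_id:
                return t
        raise KeyError(f"unknown transition {transition_id!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species_name": t.species.name,
                "precursor_mz": round(t.precursor_mz, 5),
                "adduct": t.precursor_adduct,
                "product_mz": round(t.product_mz, 5),
                "product_kind": t.product_kind.value,
                "role": t.role.value,
                "collision_energy": t.collision_energy,
                "polarity": t.polarity,
                "rt_start_min": t.rt_start,
                "rt_end_min": t.rt_end,
            }
            for t in self.transitions
        ]
        return pd.DataFrame(rows)


def enumerate_species(
    pe_bodies: Sequence,
    n_acyl_pool: Sequence[FattyAcyl],
    level: AnnotationLevel | str = AnnotationLevel.SPECIES,
) -> list[NapeSpecies]:
    """Cartesian product of PE bodies and N-acyl chains, deduplicated and sorted.

    ``pe_bodies`` entries are ``(C, D)`` tuples at species level, or
    ``(FattyAcyl, FattyAcyl)`` sn-pairs at molecular level.  Ordering is by
    total O-acyl carbons, then double bonds, then N-acyl carbons, then
    N-acyl double bonds.
    """
    level = AnnotationLevel(level)
    if not pe_bodies or not n_acyl_pool:
        raise ValueError("PE body and N-acyl pools must be non-empty")
    out: dict[NapeSpecies, None] = {}
    for body, n_acyl in itertools.product(pe_bodies, n_acyl_pool):
        if level is AnnotationLevel.MOLECULAR:
            sn1, sn2 = body
            sp = NapeSpecies.molecular(sn1, sn2, n_acyl)
        else:
            c, d = (body.carbons, body.double_bonds) if isinstance(body, FattyAcyl) else body
            sp = NapeSpecies.species(int(c), int(d), n_acyl)
        out[sp] = None
    return sorted(
        out,
        key=lambda s: (
            s.pe_carbons,
            s.pe_double_bonds,
            s.n_acyl.carbons,
            s.n_acyl.double_bonds,
            s.name,
        ),
    )


def fragment_ions(
    species: NapeSpecies,
    f2_neutral_loss: NeutralLoss | str = NeutralLoss.H3PO4,
) -> tuple[tuple[ElementalComposition, float], tuple[ElementalComposition, float]]:
    """N-acyl-specific product ions (neutral composition, protonated m/z).

    Returns ``(F1, F2)``.  Both depend only on the N-acyl chain, so every
    species sharing (n, dn) yields the same pair.
    """
    loss = NeutralLoss(f2_neutral_loss)
    if loss is NeutralLoss.NONE:
        raise ValueError("F2 requires a phosphate-side neutral loss (H3PO4 or HPO3)")
    f1 = _PHOSPHOETHANOLAMINE + n_acyl_increment(species.n_acyl)
    f2 = f1 - loss.composition
    return (f1, ion_mz(f1, "M+H")), (f2, ion_mz(f2, "M+H"))


def build_method(
    species: Sequence[NapeSpecies],
    rt,
    adduct: str = "M+H",
    collision_energy: float = 20.0,
    rt_window: float = 3.0,
    q1_window: float = 2.0,
    q3_window: float = 2.0,
    cycle_time_s: float = 1.0,
    f2_neutral_loss: NeutralLoss | str = NeutralLoss.H3PO4,
    quantifier: FragmentKind = FragmentKind.PHOSPHO_NAE,
) -> MethodTable:
    """Build the scheduled two-transition SRM method for a species list.

    ``rt`` is either a fitted retention model (anything with a
    ``predict_rt(species)`` method or callable) or an explicit mapping from
    canonical species name to retention time in minutes.
    """
    if not species:
        raise ValueError("species list must be non-empty")

    def _rt_of(sp: NapeSpecies) -> float | None:
        if isinstance(rt, Mapping):
            return rt.get(sp.name)
        if hasattr(rt, "predict_rt"):
            return rt.predict_rt(sp)
        return rt(sp)

    missing = [sp.name for sp in species if _rt_of(sp) is None]
    if missing:
        raise ValueError(f"no retention time for species: {missing}")

    adduct_obj = get_adduct(adduct)
    transitions: list[Transition] = []
    for sp in species:
        prec = ion_mz(composition(sp), adduct_obj)
        (_, f1_mz), (_, f2_mz) = fragment_ions(sp, f2_neutral_loss)
        center = float(_rt_of(sp))
        for kind, mz in (
            (FragmentKind.PHOSPHO_NAE, f1_mz),
            (FragmentKind.NAE_LIKE, f2_mz),
        ):
            transitions.append(
                Transition(
                    species=sp,
                    precursor_mz=prec,
                    precursor_adduct=adduct_obj.name,
                    product_mz=mz,
                    product_kind=kind,
                    role=Role.QUANTIFIER if kind is quantifier else Role.QUALIFIER,
                    collision_energy=collision_energy,
                    polarity="positive" if adduct_obj.charge > 0 else "negative",
                    rt_center=center,
                    rt_window=rt_window,
                )
            )
    return MethodTable(
        transitions,
        q1_window=q1_window,
        q3_window=q3_window,
        cycle_time_s=cycle_time_s,
    )


@dataclass
class IsobarGroup:
    """Species whose precursors fall inside one m/z tolerance window."""

    species: list[NapeSpecies]
    precursor_mzs: list[float]
    #: (name_i, name_j) -> True when their product-ion sets are disjoint at
    #: the Q3 tolerance, i.e. the pair is resolvable by SRM.
    pair_resolvable: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def all_resolvable(self) -> bool:
        return all(self.pair_resolvable.values())


def find_isobars(
    species: Sequence[NapeSpecies],
    mz_tolerance: float,
    adduct: str = "M+H",
    q3_tolerance: float = 1.0,
    f2_neutral_loss: NeutralLoss | str = NeutralLoss.H3PO4,
) -> list[IsobarGroup]:
    """Group species by indistinguishable precursor m/z; test SRM resolvability.

    Species join a group while their precursor m/z lies within
    ``mz_tolerance`` of the group minimum.  Within a group, a pair is
    resolvable when no product m/z of one species falls within
    ``q3_tolerance`` of any product of the other.
    """
    if mz_tolerance < 0:
        raise ValueError("mz_tolerance must be >= 0")
    entries = sorted(
        ((ion_mz(composition(sp), adduct), sp) for sp in species), key=lambda e: e[0]
    )
    groups: list[IsobarGroup] = []
    current: list[tuple[float, NapeSpecies]] = []
    for mz, sp in entries:
        if current and mz - current[0][0] > mz_tolerance:
            groups.append(_finish_group(current, q3_tolerance, f2_neutral_loss))
            current = []
        current.append((mz, sp))
    if current:
        groups.append(_finish_group(current, q3_tolerance, f2_neutral_loss))
    return groups


def _finish_group(entries, q3_tolerance, f2_loss) -> IsobarGroup:
    group = IsobarGroup(
        species=[sp for _, sp in entries], precursor_mzs=[mz for mz, _ in entries]
    )
    prods = {
        sp.name: [mz for (_, mz) in fragment_ions(sp, f2_loss)] for sp in group.species
    }
    for (a, b) in itertools.combinations(group.species, 2):
        overlap = any(
            abs(pa - pb) <= q3_tolerance for pa in prods[a.name] for pb in prods[b.name]
        )
        group.pair_resolvable[(a.name, b.name)] = not overlap
    return group


@dataclass
class SchedulingStats:
    """Concurrency profile and per-transition dwell for a scheduled method."""

    times: np.ndarray  # minutes
    concurrency: np.ndarray  # transitions acquiring at each grid time
    dwell_ms: dict[str, float]  # transition_id -> cycle_time / concurrency at center
    median_dwell_ms: float
    max_concurrency: int


def scheduling_stats(method: MethodTable, time_grid: np.ndarray | None = None) -> SchedulingStats:
    """Concurrent-transition counts over time and the resulting dwell times.

    Dwell for a transition is the cycle time split evenly among all
    transitions whose windows contain its retention-window center.
    """
    if method.cycle_time_s <= 0:
        raise ValueError("cycle_time_s must be positive")
    starts = np.array([t.rt_start for t in method.transitions])
    ends = np.array([t.rt_end for t in method.transitions])
    if time_grid is None:
        lo, hi = float(starts.min()), float(ends.max())
        time_grid = np.linspace(lo, hi, 721)
    time_grid = np.asarray(time_grid, dtype=float)
    conc = (
        (time_grid[:, None] >= starts[None, :]) & (time_grid[:, None] <= ends[None, :])
    ).sum(axis=1)
    dwell: dict[str, float] = {}
    for t in method.transitions:
        c = int(((starts <= t.rt_center) & (ends >= t.rt_center)).sum())
        dwell[t.transition_id] = 1000.0 * method.cycle_time_s / c
    return SchedulingStats(
        times=time_grid,
        concurrency=conc.astype(int),
        dwell_ms=dwell,
        median_dwell_ms=float(np.median(list(dwell.values()))),
        max_concurrency=int(conc.max()) if conc.size else 0,
    )


_CSV_COLUMNS = [
    "species_name",
    "precursor_mz",
    "adduct",
    "product_mz",
    "product_kind",
    "role",
    "collision_energy",
    "polarity",
    "rt_start_min",
    "rt_end_min",
]


def write_transition_list(method: MethodTable, destination: str | Path) -> None:
    """Write the vendor-neutral transition-list CSV (m/z to 5 decimals)."""
    frame = method.to_frame()
    frame["precursor_mz"] = frame["precursor_mz"].map(lambda v: f"{v:.5f}")
    frame["product_mz"] = frame["product_mz"].map(lambda v: f"{v:.5f}")
    frame.to_csv(destination, index=False, columns=_CSV_COLUMNS)


def read_transition_list(
    source: str | Path,
    q1_window: float = 2.0,
    q3_window: float = 2.0,
    cycle_time_s: float = 1.0,
) -> MethodTable:
    """Read a transition-list CSV back into a :class:`MethodTable`."""
    frame = pd.read_csv(source)
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"transition list missing columns: {sorted(missing)}")
    transitions = [
        Transition(
            species=parse_name(row.species_name),
            precursor_mz=float(row.precursor_mz),
            precursor_adduct=row.adduct,
            product_mz=float(row.product_mz),
            product_kind=FragmentKind(row.product_kind),
            role=Role(row.role),
            collision_energy=float(row.collision_energy),
            polarity=row.polarity,
            rt_center=(float(row.rt_start_min) + float(row.rt_end_min)) / 2,
            rt_window=float(row.rt_end_min) - float(row.rt_start_min),
        )
        for row in frame.itertuples()
    ]
    return MethodTable(
        transitions, q1_window=q1_window, q3_window=q3_window, cycle_time_s=cycle_time_s
    )
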