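"""Gamete and F2-family simulation under a Haldane (no-interference) model.

Meiosis is simulated as a Markov walk along each linkage group of the
genetic map: the source haplotype of the first marker in a group is chosen
with probability 1/2, and between adjacent markers the source switches with
probability equal to the Haldane recombination fraction of the inter-marker
distance.  This is the exact marginal law of crossovers without
interference, so explicit crossover-point placement is unnecessary.
Linkage groups segregate independently.  Normal meiotic segregation is
assumed throughout: no mutation, no distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng, spawn_seeds
from .popsim import GeneticMap, GenotypeMatrix, Panel

__all__ = [
    "PhasedIndividual",
    "F2Family",
    "haldane_r",
    "simulate_gamete",
    "simulate_gametes",
    "make_f2_family",
    "sample_parents_and_families",
]


@dataclass
class PhasedIndividual:
    """A diploid individual as two binary haplotypes aligned to a map."""

    haplotypes: np.ndarray          # (2, p) uint8
    parent_ids: tuple[str, str] | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_markers)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


@dataclass
class F2Family:
    """An interspecific F2 family: two founders, F1 generation, F2 genotypes."""

    parent_a_id: str
    parent_b_id: str
    f1: list[PhasedIndividual]
    f2: GenotypeMatrix
    gmap: GeneticMap
    family_id: str = "F2"

    def __post_init__(self):
        if self.f2.coding != "discrete_012":
            raise ValueError("F2 genotypes must be discrete_012")


def haldane_r(distance_cm) -> np.ndarray | float:
    """Haldane mapping function: r = (1 - exp(-2 d / 100)) / 2.

    Maps genetic distance in centimorgans to a recombination fraction in
    [0, 0.5); assumes no crossover interference.  Accepts scalars or arrays.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(distance_cm) else r


def _switch_probs(gmap: GeneticMap) -> np.ndarray:
    """Per-marker source-switch probability for the meiosis Markov walk.

    The first marker of every linkage group gets probability 1/2 (fresh
    fair choice, making groups independent); subsequent markers get the
    Haldane fraction of the distance to the previous marker.
    """
    q = np.empty(gmap.n_markers)
    for sl in gmap.group_slices():
        pos = gmap.position_cm[sl]
        q[sl.start] = 0.5
        if sl.stop - sl.start > 1:
            q[sl.start + 1 : sl.stop] = haldane_r(np.diff(pos))
    return q


def simulate_gametes(
    parent: PhasedIndividual, gmap: GeneticMap, n: int, rng=None
) -> np.ndarray:
    """Simulate ``n`` gametes from one parent; returns (n, p) binary array."""
    if parent.n_markers != gmap.n_markers:
        raise ValueError(
            f"parent has {parent.n_markers} markers but map has {gmap.n_markers}"
        )
    rng = as_rng(rng)
    q = _switch_probs(gmap)
    switches = rng.random((n, gmap.n_markers)) < q
    source = np.cumsum(switches, axis=1) & 1   # 0/1 haplotype index per marker
    return np.where(source == 0, parent.haplotypes[0], parent.haplotypes[1]).astype(
        np.uint8
    )


def simulate_gamete(parent: PhasedIndividual, gmap: GeneticMap, rng=None) -> np.ndarray:
    """Simulate a single gamete (1-D binary haplotype over map markers)."""
    return simulate_gametes(parent, gmap, 1, rng)[0]


def make_f2_family(
    parent_a: PhasedIndividual,
    parent_b: PhasedIndividual,
    gmap: GeneticMap,
    n_f1: int = 50,
    n_f2: int = 216,
    seed=None,
    family_id: str = "F2",
    parent_a_id: str = "A",
    parent_b_id: str = "B",
) -> F2Family:
    """Cross two founders, intermate the F1, and genotype the F2.

    Each F1 receives one gamete from each founder.  Each F2 individual is
    produced by two distinct F1 parents drawn uniformly at random (selfing
    disallowed), one gamete from each.  Deterministic given the seed.
    """
    if parent_a.n_markers != gmap.n_markers or parent_b.n_markers != gmap.n_markers:
        raise ValueError("parents must be phased on the family map")
    if n_f1 < 2:
        raise ValueError("cannot intermate fewer than 2 F1 individuals")
    if n_f2 < 1:
        raise ValueError("n_f2 must be positive")
    rng = as_rng(seed)

    gam_a = simulate_gametes(parent_a, gmap, n_f1, rng)
    gam_b = simulate_gametes(parent_b, gmap, n_f1, rng)
    f1 = [
        PhasedIndividual(
            haplotypes=np.stack([gam_a[i], gam_b[i]]),
            parent_ids=(parent_a_id, parent_b_id),
        )
        for i in range(n_f1)
    ]

    # draw F2 parent pairs uniformly, rejecting selfing
    first = rng.integers(0, n_f1, size=n_f2)
    second = rng.integers(0, n_f1, size=n_f2)
    while np.any(first == second):
        clash = first == second
        second[clash] = rng.integers(0, n_f1, size=int(clash.sum()))

    # batch gamete simulation per F1 parent
    f2_h1 = np.empty((n_f2, gmap.n_markers), dtype=np.uint8)
    f2_h2 = np.empty((n_f2, gmap.n_markers), dtype=np.uint8)
    for k in range(n_f1):
        m1 = np.flatnonzero(first == k)
        m2 = np.flatnonzero(second == k)
        need = len(m1) + len(m2)
        if need == 0:
            continue
        g = simulate_gametes(f1[k], gmap, need, rng)
        f2_h1[m1] = g[: len(m1)]
        f2_h2[m2] = g[len(m1):]

    dosage = (f2_h1 + f2_h2).astype(float)
    f2 = GenotypeMatrix(
        values=dosage,
        coding="discrete_012",
        individual_ids=[f"{family_id}_{i + 1}" for i in range(n_f2)],
        marker_ids=list(gmap.marker_id),
    )
    return F2Family(
        parent_a_id=parent_a_id,
        parent_b_id=parent_b_id,
        f1=f1,
        f2=f2,
        gmap=gmap,
        family_id=family_id,
    )


def _phased_from_panel(panel: Panel, idx: int, rng: np.random.Generator) -> PhasedIndividual:
    """Extract a phased founder; unphased dosages are phased randomly once.

    Random phasing is exact for single-locus F2 genotype distributions
    (phase-invariant); founder LD is only approximate in that case.
    """
    if panel.haplotypes is not None:
        h = panel.haplotypes[idx]
    else:
        dos = panel.genotypes.values[idx]
        if not np.isin(dos, (0.0, 1.0, 2.0)).all():
            raise ValueError("cannot phase non-discrete dosages")
        h0 = (dos == 2).astype(np.uint8)
        het = dos == 1
        coin = (rng.random(het.sum()) < 0.5).astype(np.uint8)
        h0[het] = coin
        h1 = (dos - h0).astype(np.uint8)
        h = np.stack([h0, h1])
    return PhasedIndividual(haplotypes=h)


def sample_parents_and_families(
    panel_a: Panel,
    panel_b: Panel,
    gmap: GeneticMap,
    n_families: int = 50,
    n_f1: int = 50,
    n_f2: int = 216,
    seed: int = 0,
) -> list[F2Family]:
    """Simulate interspecific F2 families from randomly drawn panel parents.

    For every family one parent is drawn uniformly from each panel
    (independently across families) and an F2 family is built with
    :func:`make_f2_family`.  Parent ids are recorded on each family.
    """
    if panel_a.n_individuals == 0 or panel_b.n_individuals == 0:
        raise ValueError("both panels must be non-empty")
    if n_families < 1:
        raise ValueError("n_families must be positive")
    seeds = spawn_seeds(seed, n_families + 1)
    pick = as_rng(seeds[0])
    families = []
    for f in range(n_families):
        ia = int(pick.integers(0, panel_a.n_individuals))
        ib = int(pick.integers(0, panel_b.n_individuals))
        child = as_rng(seeds[f + 1])
        pa = _phased_from_panel(panel_a, ia, child)
        pb = _phased_from_panel(panel_b, ib, child)
        families.append(
            make_f2_family(
                pa,
                pb,
                gmap,
                n_f1=n_f1,
                n_f2=n_f2,
                seed=child,
                family_id=f"fam{f + 1}",
                parent_a_id=panel_a.genotypes.individual_ids[ia],
                parent_b_id=panel_b.genotypes.individual_ids[ib],
            )
        )
    return families
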