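"""Synthetic structured diversity panels and genetic maps.

Generates phased diploid panels with subpopulation structure under the
Balding–Nichols model: per marker an ancestral allele frequency ``p`` is
drawn, each subpopulation's frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (mean ``p``, differentiation controlled by
``F`` = Fst), and haplotype alleles are Bernoulli draws at the
subpopulation frequency.  Two related species panels are produced by
applying one extra Balding–Nichols divergence step to a common ancestral
frequency vector before the within-species structure is laid down.

These panels stand in for real germplasm diversity panels (two Miscanthus
species panels in the motivating study); they reproduce the qualitative
features that matter downstream — subpopulation structure recoverable by
PCA, reduced cross-species kinship — without attempting LD-realistic
haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "Panel",
    "simulate_map",
    "simulate_panel",
    "simulate_species_pair",
]


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions on linkage groups, in centimorgans.

    Positions are strictly increasing within each linkage group and marker
    ids are unique.
    """

    marker_id: np.ndarray        # str array, shape (p,)
    linkage_group: np.ndarray    # int array, shape (p,), values in 1..L
    position_cm: np.ndarray      # float array, shape (p,)

    def __post_init__(self):
        if len(self.marker_id) != len(self.linkage_group) or len(self.marker_id) != len(
            self.position_cm
        ):
            raise ValueError("map columns must have equal length")
        if len(np.unique(self.marker_id)) != len(self.marker_id):
            raise ValueError("marker ids must be unique")
        if np.any(self.position_cm < 0):
            raise ValueError("positions must be non-negative")
        for lg in np.unique(self.linkage_group):
            where = np.flatnonzero(self.linkage_group == lg)
            if len(where) and (where[-1] - where[0] + 1) != len(where):
                raise ValueError(f"markers of linkage group {lg} are not contiguous")
            pos = self.position_cm[where]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing within linkage group {lg}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def n_linkage_groups(self) -> int:
        return len(np.unique(self.linkage_group))

    def group_slices(self) -> list[slice]:
        """Contiguous index slice per linkage group (markers are stored grouped)."""
        out = []
        lgs = self.linkage_group
        start = 0
        for i in range(1, len(lgs) + 1):
            if i == len(lgs) or lgs[i] != lgs[start]:
                out.append(slice(start, i))
                start = i
        return out


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with ids and coding metadata.

    ``coding`` is ``"discrete_012"`` (entries in {0,1,2}) or ``"dosage_01"``
    (posterior-mean dosages in [0,1]).
    """

    values: np.ndarray
    coding: str
    individual_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.coding not in ("discrete_012", "dosage_01"):
            raise ValueError(f"unknown coding {self.coding!r}")
        n, p = self.values.shape
        if n != len(self.individual_ids):
            raise ValueError("row count does not match individual id count")
        if p != len(self.marker_ids):
            raise ValueError("column count does not match marker id count")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing/non-finite dosages are not allowed")
        if self.coding == "discrete_012":
            if not np.isin(self.values, (0.0, 1.0, 2.0)).all():
                raise ValueError("discrete_012 entries must be in {0,1,2}")
        else:
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValueError("dosage_01 entries must lie in [0,1]")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class Panel:
    """A diversity panel: dosages, optional phased haplotypes, structure labels.

    ``haplotypes`` has shape (n, 2, p) with binary entries; when present its
    sum over the second axis equals the dosage matrix.  ``species_tag`` is
    "A" or "B" (the two species panels of an interspecific design).
    """

    genotypes: GenotypeMatrix
    haplotypes: np.ndarray | None
    subpop_label: np.ndarray
    species_tag: str = "A"

    def __post_init__(self):
        if self.species_tag not in ("A", "B"):
            raise ValueError("species_tag must be 'A' or 'B'")
        if len(self.subpop_label) != self.genotypes.n_individuals:
            raise ValueError("subpop labels must cover all individuals")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (
                self.genotypes.n_individuals,
                2,
                self.genotypes.n_markers,
            ):
                raise ValueError("haplotype array shape mismatch")
            if not np.array_equal(
                self.haplotypes.sum(axis=1), self.genotypes.values
            ):
                raise ValueError("haplotypes do not sum to dosages")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals


def simulate_map(
    n_markers: int,
    n_linkage_groups: int,
    length_cm: float,
    seed=None,
) -> GeneticMap:
    """Draw a genetic map with markers spread across linkage groups.

    Markers are allocated as evenly as possible across linkage groups
    (remainder goes to the first groups); within a group positions are
    i.i.d. Uniform(0, length_cm), sorted, and nudged apart if a floating
    point tie occurs.

    Parameters
    ----------
    n_markers, n_linkage_groups : int
        Totals; ``n_markers >= n_linkage_groups >= 1``.
    length_cm : float
        Length of every linkage group in centimorgans.
    """
    if n_markers < 1 or n_linkage_groups < 1:
        raise ValueError("n_markers and n_linkage_groups must be positive")
    if n_markers < n_linkage_groups:
        raise ValueError("need at least one marker per linkage group")
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    rng = as_rng(seed)

    base, extra = divmod(n_markers, n_linkage_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(n_linkage_groups)]

    ids, lgs, pos = [], [], []
    counter = 1
    for g, size in enumerate(sizes, start=1):
        x = np.sort(rng.uniform(0.0, length_cm, size=size))
        # break exact ties (probability ~0, but the strict-increase invariant is hard)
        for i in range(1, size):
            if x[i] <= x[i - 1]:
                x[i] = np.nextafter(x[i - 1], np.inf)
        ids.extend(f"M{counter + i}" for i in range(size))
        counter += size
        lgs.extend([g] * size)
        pos.append(x)
    return GeneticMap(
        marker_id=np.array(ids, dtype=object),
        linkage_group=np.array(lgs, dtype=int),
        position_cm=np.concatenate(pos) if pos else np.empty(0),
    )


def _balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols drift step: draw frequencies with mean p, Fst fst."""
    if fst == 0:
        return p.copy()
    if fst >= 1:
        # full fixation limit: alleles fixed at frequency-p odds
        return (rng.random(p.shape) < p).astype(float)
    scale = (1.0 - fst) / fst
    # frequencies already fixed at 0/1 are absorbing under drift
    interior = (p > 0) & (p < 1)
    out = p.copy()
    out[interior] = rng.beta(p[interior] * scale, (1.0 - p[interior]) * scale)
    return out


def _split_evenly(n: int, k: int) -> np.ndarray:
    """Subpopulation label per individual: even split, remainder to first pops."""
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    return np.repeat(np.arange(1, k + 1), sizes)


def _draw_panel(
    base_freq: np.ndarray,
    n_individuals: int,
    n_subpops: int,
    fst: float,
    rng: np.random.Generator,
    species_tag: str,
    id_prefix: str,
    marker_ids: list[str],
) -> Panel:
    labels = _split_evenly(n_individuals, n_subpops)
    subpop_freq = np.stack(
        [_balding_nichols(base_freq, fst, rng) for _ in range(n_subpops)]
    )  # (K, p)
    freq_per_ind = subpop_freq[labels - 1]  # (n, p)
    haplos = (
        rng.random((n_individuals, 2, len(base_freq))) < freq_per_ind[:, None, :]
    ).astype(np.uint8)
    dosage = haplos.sum(axis=1).astype(float)
    geno = GenotypeMatrix(
        values=dosage,
        coding="discrete_012",
        individual_ids=[f"{id_prefix}{i + 1}" for i in range(n_individuals)],
        marker_ids=list(marker_ids),
    )
    return Panel(
        genotypes=geno, haplotypes=haplos, subpop_label=labels, species_tag=species_tag
    )


def simulate_panel(
    n_individuals: int,
    gmap: GeneticMap,
    n_subpops: int,
    fst: float,
    seed=None,
    species_tag: str = "A",
) -> Panel:
    """Simulate one structured panel under the Balding–Nichols model.

    Ancestral frequencies are Uniform(0.05, 0.95) per marker; each of the
    ``n_subpops`` subpopulations gets a drifted frequency vector with
    differentiation ``fst``; individuals are split evenly across
    subpopulations and their two haplotypes drawn independently.
    Markers that come out monomorphic are retained.
    """
    if n_subpops < 1 or n_individuals < n_subpops:
        raise ValueError("need n_individuals >= n_subpops >= 1")
    if not (0 < fst < 1):
        raise ValueError("fst must lie strictly in (0, 1)")
    rng = as_rng(seed)
    p = rng.uniform(0.05, 0.95, size=gmap.n_markers)
    prefix = "A" if species_tag == "A" else "B"
    return _draw_panel(
        p, n_individuals, n_subpops, fst, rng, species_tag, prefix, list(gmap.marker_id)
    )


def simulate_species_pair(
    n_a: int,
    n_b: int,
    gmap: GeneticMap,
    n_subpops_each: int,
    fst_within: float,
    divergence: float,
    seed=None,
) -> tuple[Panel, Panel]:
    """Simulate two related species panels sharing an ancestral frequency vector.

    One ancestral vector is drawn; each species' base frequencies are one
    Balding–Nichols step with parameter ``divergence`` away from it, after
    which within-species subpopulation structure (``fst_within``) is applied
    exactly as in :func:`simulate_panel`.  ``divergence = 0`` makes both
    species share base frequencies.
    """
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must lie in [0, 1]")
    if n_subpops_each < 1 or n_a < n_subpops_each or n_b < n_subpops_each:
        raise ValueError("need n individuals >= n_subpops_each >= 1 in both panels")
    if not (0 < fst_within < 1):
        raise ValueError("fst_within must lie strictly in (0, 1)")
    rng = as_rng(seed)
    p = rng.uniform(0.05, 0.95, size=gmap.n_markers)
    base_a = _balding_nichols(p, divergence, rng)
    base_b = _balding_nichols(p, divergence, rng)
    marker_ids = list(gmap.marker_id)
    panel_a = _draw_panel(base_a, n_a, n_subpops_each, fst_within, rng, "A", "A", marker_ids)
    panel_b = _draw_panel(base_b, n_b, n_subpops_each, fst_within, rng, "B", "B", marker_ids)
    return panel_a, panel_b
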