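"""Trait simulation under QTN-sharing scenarios with heritability calibration.

Traits are controlled by a small set of quantitative trait nucleotides
(QTNs) drawn from the mapped markers.  Five scenarios govern how the QTN
sets of the two species panels relate:

=============  ==========================================================
``S.QTN``      same QTNs, same effects in both panels (scenario 1)
``P.QTN``      half the QTNs shared (same effects), half panel-specific
               (scenario 2)
``D.QTN``      completely different QTNs per panel (scenario 3)
``D.QTN.Msi``  different QTNs; panel A draws large effects U(0.5, 0.99),
               panel B small effects U(0, 0.25) (scenario 4)
``D.QTN.Msa``  the mirror image: large effects in panel B (scenario 5)
=============  ==========================================================

Architecture codes count QTNs per genetic mechanism: ``A20D0E0`` is 20
additive QTNs only; ``A20D4E0`` adds 4 dominance QTNs; ``A20D0E4`` adds 4
loci engaged in additive-by-additive epistasis (2 disjoint pairs).

Genetic values use the {-1, 0, 1} marker code x = dosage - 1:

    g = sum_j a_j x_j + sum_j d_j 1{dosage_j = 1} + sum_k w_k x_{k1} x_{k2}

Phenotypes are y = g + e with e ~ N(0, sigma_e^2) and sigma_e^2 chosen so
that the broad-sense heritability Var(g) / (Var(g) + sigma_e^2) hits a
target: 0.60 in the diversity panels and 0.37 in F2 families, the F2 noise
variance being recomputed per family from that family's genetic variance.
In F2 families all segregating QTNs of both panels contribute (shared QTNs
once); QTNs that do not segregate contribute no variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng, spawn_seeds
from .meiosis import F2Family
from .popsim import GenotypeMatrix, Panel

__all__ = [
    "SCENARIOS",
    "ARCHITECTURES",
    "PANEL_H2",
    "F2_H2",
    "QTNSet",
    "TraitArchitecture",
    "SimulatedTrait",
    "DegenerateTraitError",
    "select_qtns",
    "genetic_value",
    "add_noise_to_target_h2",
    "simulate_trait_suite",
]

SCENARIOS = ("S.QTN", "P.QTN", "D.QTN", "D.QTN.Msi", "D.QTN.Msa")
ARCHITECTURES = ("A20D0E0", "A20D4E0", "A20D0E4")

#: heritability targets for diversity panels and F2 families
PANEL_H2 = 0.60
F2_H2 = 0.37

_SCENARIO_ALIASES = {"1": "S.QTN", "2": "P.QTN", "3": "D.QTN", "4": "D.QTN.Msi", "5": "D.QTN.Msa"}


class DegenerateTraitError(ValueError):
    """Raised when a trait has zero genetic variance but needs noise calibration."""


@dataclass
class QTNSet:
    """QTNs and effects for one panel."""

    additive_idx: np.ndarray       # (n_add,) marker indices
    additive_eff: np.ndarray       # (n_add,)
    dominance_idx: np.ndarray      # (n_dom,)
    dominance_eff: np.ndarray
    epistasis_pairs: np.ndarray    # (n_pairs, 2) marker indices
    epistasis_eff: np.ndarray      # (n_pairs,)


@dataclass
class TraitArchitecture:
    """Per-panel QTN sets under a named scenario and architecture code."""

    scenario: str
    architecture: str
    panel_a: QTNSet
    panel_b: QTNSet
    seed: int | None = None

    def union(self) -> QTNSet:
        """QTNs contributing in an F2 of the two panels: shared QTNs count once.

        A QTN is shared when the same locus (or locus pair) carries the same
        effect in both panels, which is how shared QTNs are constructed.
        """
        def merge(idx_a, eff_a, idx_b, eff_b, pair=False):
            seen: dict = {}
            for idx, eff in ((idx_a, eff_a), (idx_b, eff_b)):
                for i in range(len(eff)):
                    key = tuple(idx[i]) if pair else int(idx[i])
                    if key not in seen:
                        seen[key] = eff[i]
                    # same locus with a different effect: both contribute
                    elif seen[key] != eff[i]:
                        seen[key] = seen[key] + eff[i]
            if not seen:
                shape = (0, 2) if pair else (0,)
                return np.empty(shape, dtype=int), np.empty(0)
            keys = list(seen)
            idx = np.array(keys, dtype=int)
            return idx, np.array([seen[k] for k in keys])

        a, b = self.panel_a, self.panel_b
        add_i, add_e = merge(a.additive_idx, a.additive_eff, b.additive_idx, b.additive_eff)
        dom_i, dom_e = merge(a.dominance_idx, a.dominance_eff, b.dominance_idx, b.dominance_eff)
        epi_i, epi_e = merge(
            a.epistasis_pairs, a.epistasis_eff, b.epistasis_pairs, b.epistasis_eff, pair=True
        )
        return QTNSet(add_i, add_e, dom_i, dom_e, epi_i, epi_e)


@dataclass
class SimulatedTrait:
    """Genetic values, phenotypes and heritability bookkeeping for one trait."""

    genetic_values: np.ndarray
    phenotypes: np.ndarray
    target_h2: float
    noise_variance: float
    realized_h2: float


def _parse_architecture(architecture: str) -> tuple[int, int, int]:
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}; expected one of {ARCHITECTURES}")
    n_add = int(architecture[1:3])
    n_dom = int(architecture[4])
    n_epi = int(architecture[6])
    return n_add, n_dom, n_epi


def _draw_effects(n: int, lo: float, hi: float, rng, signed: bool) -> np.ndarray:
    eff = rng.uniform(lo, hi, size=n)
    if signed:
        eff *= rng.choice((-1.0, 1.0), size=n)
    return eff


def select_qtns(
    scenario: str,
    n_markers: int,
    architecture: str = "A20D0E0",
    seed=None,
    signed_effects: bool = True,
) -> TraitArchitecture:
    """Choose QTN loci and effects for both panels under a scenario.

    Loci for the additive, dominance and epistatic mechanisms are disjoint
    within a panel.  Under ``P.QTN``, half of each mechanism's QTNs are
    shared between panels (identical locus and effect), the rest are
    panel-specific and disjoint between panels.  Under the ``D.*`` scenarios
    the two panels' QTN sets are completely disjoint.  Effects are uniform
    draws — U(0,1) except in the large/small scenarios where the named panel
    draws U(0.5, 0.99) and the other U(0, 0.25) — with a random sign per
    effect when ``signed_effects`` (magnitude ranges only constrain |effect|).
    """
    scenario = _SCENARIO_ALIASES.get(str(scenario), scenario)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    n_add, n_dom, n_epi = _parse_architecture(architecture)
    n_loci = n_add + n_dom + n_epi
    shared = scenario in ("S.QTN", "P.QTN")
    # D.* scenarios need two disjoint sets; P.QTN needs 1.5 sets
    need = n_loci if scenario == "S.QTN" else (n_loci + n_loci // 2 if scenario == "P.QTN" else 2 * n_loci)
    if need > n_markers:
        raise ValueError(f"scenario {scenario} needs {need} distinct loci but only {n_markers} markers exist")
    rng = as_rng(seed)

    if scenario in ("D.QTN.Msi", "D.QTN.Msa"):
        large, small = (0.5, 0.99), (0.0, 0.25)
        range_a = large if scenario == "D.QTN.Msi" else small
        range_b = small if scenario == "D.QTN.Msi" else large
    else:
        range_a = range_b = (0.0, 1.0)

    def build(idx: np.ndarray, lo: float, hi: float) -> QTNSet:
        add = idx[:n_add]
        dom = idx[n_add : n_add + n_dom]
        epi = idx[n_add + n_dom :]
        return QTNSet(
            additive_idx=add,
            additive_eff=_draw_effects(n_add, lo, hi, rng, signed_effects),
            dominance_idx=dom,
            dominance_eff=_draw_effects(n_dom, lo, hi, rng, signed_effects),
            epistasis_pairs=epi.reshape(-1, 2),
            epistasis_eff=_draw_effects(n_epi // 2, lo, hi, rng, signed_effects),
        )

    if scenario == "S.QTN":
        idx = rng.choice(n_markers, size=n_loci, replace=False)
        qtn_a = build(idx, *range_a)
        qtn_b = QTNSet(
            additive_idx=qtn_a.additive_idx.copy(),
            additive_eff=qtn_a.additive_eff.copy(),
            dominance_idx=qtn_a.dominance_idx.copy(),
            dominance_eff=qtn_a.dominance_eff.copy(),
            epistasis_pairs=qtn_a.epistasis_pairs.copy(),
            epistasis_eff=qtn_a.epistasis_eff.copy(),
        )
    elif scenario == "P.QTN":
        # shared half + a private half per panel, all loci distinct
        half_add, half_dom, half_epi = n_add // 2, n_dom // 2, n_epi // 2
        # epistatic loci shared in whole pairs: half the pairs shared
        half_epi -= half_epi % 2
        n_shared = half_add + half_dom + half_epi
        n_private = n_loci - n_shared
        idx = rng.choice(n_markers, size=n_shared + 2 * n_private, replace=False)

        def interleave(priv):
            """Assemble a full-size index vector: shared part first per mechanism."""
            sh = idx[:n_shared]
            out = np.concatenate([
                sh[:half_add], priv[: n_add - half_add],
                sh[half_add : half_add + half_dom], priv[n_add - half_add : n_add - half_add + n_dom - half_dom],
                sh[half_add + half_dom :], priv[n_add - half_add + n_dom - half_dom :],
            ])
            return out

        priv_a = idx[n_shared : n_shared + n_private]
        priv_b = idx[n_shared + n_private :]
        qtn_a = build(interleave(priv_a), *range_a)
        qtn_b = build(interleave(priv_b), *range_b)
        # overwrite the shared half of panel B with panel A's effects
        qtn_b.additive_eff[:half_add] = qtn_a.additive_eff[:half_add]
        qtn_b.dominance_eff[:half_dom] = qtn_a.dominance_eff[:half_dom]
        qtn_b.epistasis_eff[: half_epi // 2] = qtn_a.epistasis_eff[: half_epi // 2]
    else:
        idx = rng.choice(n_markers, size=2 * n_loci, replace=False)
        qtn_a = build(idx[:n_loci], *range_a)
        qtn_b = build(idx[n_loci:], *range_b)

    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return TraitArchitecture(
        scenario=scenario, architecture=architecture, panel_a=qtn_a, panel_b=qtn_b,
        seed=seed_int,
    )


def genetic_value(genotypes: GenotypeMatrix, qtns: QTNSet) -> np.ndarray:
    """Compute per-individual genetic values from a QTN set.

    Requires discrete {0,1,2} genotypes.  Additive effects act on the
    {-1,0,1} code, dominance effects on the heterozygote indicator, and
    each epistatic pair contributes its effect times the product of the two
    loci's {-1,0,1} codes.
    """
    if genotypes.coding != "discrete_012":
        raise ValueError("genetic values require discrete_012 genotypes")
    dosage = genotypes.values
    p = dosage.shape[1]
    for name, idx in (
        ("additive", qtns.additive_idx),
        ("dominance", qtns.dominance_idx),
        ("epistasis", qtns.epistasis_pairs),
    ):
        if len(idx) and np.max(idx) >= p:
            raise IndexError(f"{name} QTN index out of range for {p} markers")
    x = dosage - 1.0
    g = np.zeros(dosage.shape[0])
    if len(qtns.additive_eff):
        g += x[:, qtns.additive_idx] @ qtns.additive_eff
    if len(qtns.dominance_eff):
        g += (dosage[:, qtns.dominance_idx] == 1.0) @ qtns.dominance_eff
    if len(qtns.epistasis_eff):
        g += (
            x[:, qtns.epistasis_pairs[:, 0]] * x[:, qtns.epistasis_pairs[:, 1]]
        ) @ qtns.epistasis_eff
    return g


def add_noise_to_target_h2(g: np.ndarray, target_h2: float, seed=None) -> SimulatedTrait:
    """Add i.i.d. Gaussian noise calibrated to a broad-sense heritability target.

    sigma_e^2 = Var(g) (1 - H2) / H2, so that Var(g)/(Var(g)+sigma_e^2)
    equals the target in expectation.  The realized H2 = Var(g)/Var(y) of
    the particular noise draw is recorded.
    """
    g = np.asarray(g, dtype=float)
    if not (0 < target_h2 <= 1):
        raise ValueError("target_h2 must lie in (0, 1]")
    var_g = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
    # a constant g computed in floating point can carry ~1e-32 rounding noise
    if var_g <= 1e-12 * (1.0 + float(np.mean(g)) ** 2):
        var_g = 0.0
    if var_g == 0 and target_h2 < 1:
        raise DegenerateTraitError("genetic variance is zero; cannot calibrate noise")
    sigma_e2 = var_g * (1.0 - target_h2) / target_h2
    rng = as_rng(seed)
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=len(g)) if sigma_e2 > 0 else np.zeros(len(g))
    y = g + e
    var_y = float(np.var(y, ddof=1))
    # sampling fluctuation (cov(g, e) < 0) can push the raw ratio above 1
    # at small n; cap to keep realized_h2 a heritability
    realized = min(var_g / var_y, 1.0) if var_y > 0 else 1.0
    return SimulatedTrait(
        genetic_values=g,
        phenotypes=y,
        target_h2=target_h2,
        noise_variance=sigma_e2,
        realized_h2=realized,
    )


def simulate_trait_suite(
    panel_a: Panel,
    panel_b: Panel,
    families: list[F2Family],
    scenario: str,
    architecture: str = "A20D0E0",
    seed: int = 0,
    panel_h2: float = PANEL_H2,
    f2_h2: float = F2_H2,
    signed_effects: bool = True,
) -> dict:
    """Simulate one trait in both panels and every F2 family.

    One QTN architecture is drawn for the (scenario, architecture) pair;
    panel phenotypes are calibrated to ``panel_h2`` each, and each family is
    calibrated to ``f2_h2`` with a family-specific noise variance computed
    from that family's genetic variance over the union of both panels' QTNs.

    Returns a dict with keys ``architecture`` (:class:`TraitArchitecture`),
    ``panel_a``/``panel_b`` (:class:`SimulatedTrait`) and ``families``
    (list of :class:`SimulatedTrait`, aligned with the input families).
    """
    n_markers = panel_a.genotypes.n_markers
    if panel_b.genotypes.n_markers != n_markers or any(
        f.f2.n_markers != n_markers for f in families
    ):
        raise ValueError("panels and families must share one marker universe")
    seeds = spawn_seeds(seed, 3 + len(families))
    arch = select_qtns(
        scenario, n_markers, architecture, seed=seeds[0], signed_effects=signed_effects
    )
    out = {"architecture": arch}
    out["panel_a"] = add_noise_to_target_h2(
        genetic_value(panel_a.genotypes, arch.panel_a), panel_h2, seed=seeds[1]
    )
    out["panel_b"] = add_noise_to_target_h2(
        genetic_value(panel_b.genotypes, arch.panel_b), panel_h2, seed=seeds[2]
    )
    union = arch.union()
    fam_traits = []
    for fam, s in zip(families, seeds[3:]):
        try:
            fam_traits.append(
                add_noise_to_target_h2(genetic_value(fam.f2, union), f2_h2, seed=s)
            )
        except DegenerateTraitError as err:
            raise DegenerateTraitError(
                f"family {fam.family_id}: {err}"
            ) from err
    out["families"] = fam_traits
    return out
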