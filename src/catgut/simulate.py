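"""Synthetic longitudinal cohort generator.

Emulates the design and statistical structure of the kitten study the
analysis modules assume: 30 kittens (16 male, 14 female) from 17 litters,
assigned to four gender x neuter-age groups (7 F-EN, 7 F-CN, 8 M-EN,
8 M-CN) such that no group contains two littermates; faecal samples at
18, 30 and 42 weeks of age with one early-neutered female withdrawn after
her first sample (88 samples in total); compositional genus counts whose
per-age mean vectors are calibrated to the published average composition
(:mod:`catgut.calibration`), with Dirichlet-multinomial overdispersion, a
kitten-level random intercept on logits, an optional set of injected
per-feature age / sex / neuter log-odds-ratios (null by default), derived
KEGG-ortholog counts via genus-specific KO profiles, and genus-private
gene pools so gene richness tracks genus richness.

All randomness flows from a single root seed; each generation stage uses
``root_seed + OFFSET`` with the fixed offsets below, so stages are
individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import calibration
from .tables import FeatureTable, KeggHierarchy, StudyDesign

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "generate_design",
    "generate_counts",
    "generate_kegg_hierarchy",
    "default_effect_spec",
    "simulate_cohort",
]

# fixed seed offsets per generation stage
_OFF_DESIGN = 11
_OFF_KITTEN = 23
_OFF_COMP = 37
_OFF_KO_PROFILE = 53
_OFF_KO_COUNTS = 67
_OFF_GENES = 79
_OFF_HIERARCHY = 97

#: full-scale rarefaction reference depth (reads); desk runs scale against it
FULL_SCALE_MAX_DEPTH = 20_000_000


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_kittens: int = 30
    n_female: int = 14
    n_male: int = 16
    n_litters: int = 17
    #: kittens per (sex, neuter) group
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"F-EN": 7, "F-CN": 7, "M-EN": 8, "M-CN": 8})
    ages: Sequence[int] = (18, 30, 42)
    #: (kitten index within the F-EN group, ages missing); default mirrors a
    #: single early-neutered female withdrawn after the first sampling
    dropouts: Sequence[tuple[str, Sequence[int]]] = (("F-EN:0", (30, 42)),)
    #: per-sample annotated-read range; desk-scale default. Full scale
    #: (cluster only) would be 2.3e7–9.1e7.
    reads_range: tuple[int, int] = (23_000, 91_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes.values()) != self.n_kittens:
            raise ValueError("group sizes must sum to n_kittens")
        n_f = sum(v for k, v in self.group_sizes.items() if k.startswith("F"))
        if n_f != self.n_female or self.n_kittens - n_f != self.n_male:
            raise ValueError("group sizes inconsistent with sex totals")
        # no group may need two kittens of one litter
        if max(self.group_sizes.values()) > self.n_litters:
            raise ValueError("litter constraint infeasible: a group exceeds n_litters")
        if self.n_kittens > 4 * self.n_litters:
            raise ValueError("more kittens than four groups x litters can hold")


def generate_design(spec: CohortSpec) -> StudyDesign:
    """Draw a study design satisfying the litter constraint.

    Litters are sized so that littermates always land in different groups
    (greedy assignment to the groups with most unassigned kittens), which
    is always feasible under the :class:`CohortSpec` invariants.
    """
    rng = np.random.default_rng(spec.seed + _OFF_DESIGN)
    groups = list(spec.group_sizes)
    remaining = dict(spec.group_sizes)

    # litter sizes: as many 2-kitten litters as kittens allow, rest singletons
    n_twos = spec.n_kittens - spec.n_litters
    if n_twos < 0:
        raise ValueError("more litters than kittens")
    sizes = [2] * n_twos + [1] * (spec.n_litters - n_twos)
    rng.shuffle(sizes)

    kitten_rows = []
    counters = {g: 0 for g in groups}
    k_idx = 0
    for li, size in enumerate(sizes, start=1):
        # groups with most unassigned kittens first; random tie-break
        order = sorted(groups, key=lambda g: (-remaining[g], rng.random()))
        chosen = [g for g in order if remaining[g] > 0][:size]
        if len(chosen) < size:
            raise ValueError("infeasible litter assignment")
        for g in chosen:
            remaining[g] -= 1
            sex, neuter = g.split("-")
            k_idx += 1
            kitten_rows.append({
                "kitten_id": f"K{k_idx:02d}", "litter_id": f"L{li:02d}",
                "sex": sex, "neuter_group": neuter,
                "group": g, "group_index": counters[g],
            })
            counters[g] += 1

    dropped: dict[str, set[int]] = {}
    for key, missing_ages in spec.dropouts:
        if ":" in str(key):
            g, idx = str(key).split(":")
            match = [r for r in kitten_rows
                     if r["group"] == g and r["group_index"] == int(idx)]
            if not match:
                raise ValueError(f"dropout spec {key!r} matches no kitten")
            kid = match[0]["kitten_id"]
        else:
            kid = str(key)
        dropped[kid] = set(int(a) for a in missing_ages)

    lo, hi = spec.reads_range
    rows = []
    for r in kitten_rows:
        for age in spec.ages:
            if age in dropped.get(r["kitten_id"], ()):
                continue
            rows.append({
                "sample_id": f"{r['kitten_id']}w{age}",
                "kitten_id": r["kitten_id"], "litter_id": r["litter_id"],
                "sex": r["sex"], "neuter_group": r["neuter_group"],
                "age_week": age,
                "denominator": int(rng.integers(lo, hi + 1)),
            })
    return StudyDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# composition / effects

@dataclass
class EffectSpec:
    """Statistical structure of the generated abundance data.

    ``genus_means`` gives the per-age mean composition (genera in rows,
    one column per sampling age, columns summing to 1).  ``theta`` is the
    Dirichlet-multinomial concentration (larger = less overdispersion).
    ``kitten_sd`` is the SD of a kitten-level random intercept applied on
    the logit scale, shared across ages, inducing within-kitten
    correlation.  ``age_log_or`` maps a feature to its injected log-odds
    shifts at the second and third age relative to the first (applied on
    top of ``genus_means``); sex/neuter shifts are analogous and default
    to zero everywhere, matching a cohort with no true gender or
    neuter-age effect.
    """

    genus_means: pd.DataFrame
    theta: float = 50.0
    kitten_sd: float = 0.3
    age_log_or: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    sex_log_or: Mapping[str, float] = field(default_factory=dict)
    neuter_log_or: Mapping[str, float] = field(default_factory=dict)
    ko_age_log_or: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_ko: int = 400
    ko_density: float = 0.15
    genes_per_genus: float = 40.0
    genus_phylum: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        sums = self.genus_means.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("each genus mean-composition column must sum to 1")


def _rare_tail_weights(n: int, x: float = 0.95) -> np.ndarray:
    """Log-series weights w_k ∝ x^k / k for a simulated rare tail."""
    k = np.arange(1, n + 1, dtype=float)
    w = x ** k / k
    return w / w.sum()


def default_effect_spec(seed: int = 0, theta: float = 50.0,
                        kitten_sd: float = 0.3, n_ko: int = 400) -> EffectSpec:
    """Per-age genus means calibrated to the published composition table.

    Displayed genera take their printed means; per phylum, the gap between
    the printed phylum mean and the displayed-genus sum is spread over a
    log-series tail of hidden genera of that phylum; mass outside the five
    phyla goes to a tail of "Other"-phylum genera.  Columns sum to 1.
    """
    gmeans = calibration.genus_means_percent()          # percent
    pmeans = calibration.phylum_means_percent()
    g2p = dict(calibration.genus_to_phylum())
    ages = list(calibration.AGES)

    n_hidden = {"Actinobacteria": 8, "Bacteroidetes": 8, "Firmicutes": 12,
                "Proteobacteria": 10, "Spirochaetes": 3}
    rows: dict[str, list[float]] = {g: list(gmeans.loc[g]) for g in gmeans.index}
    for phylum, n_h in n_hidden.items():
        displayed = gmeans.loc[[g for g in gmeans.index if g2p[g] == phylum]].sum(axis=0)
        hidden_mass = pmeans.loc[phylum] - displayed    # per age, percent
        w = _rare_tail_weights(n_h)
        for i in range(n_h):
            name = f"{phylum}_rare{i + 1:02d}"
            rows[name] = [hidden_mass[a] * w[i] for a in ages]
            g2p[name] = phylum
    other_mass = 100.0 - pmeans.sum(axis=0)             # outside the 5 phyla
    n_other = 25
    w = _rare_tail_weights(n_other)
    for i in range(n_other):
        name = f"Other_rare{i + 1:02d}"
        rows[name] = [other_mass[a] * w[i] for a in ages]
        g2p[name] = "Other"

    means = pd.DataFrame(rows, index=ages).T / 100.0
    means = means / means.sum(axis=0)                   # exact renormalisation
    means.index.name = "genus"
    return EffectSpec(genus_means=means, theta=theta, kitten_sd=kitten_sd,
                      n_ko=n_ko, genus_phylum=g2p, seed=seed)


def _shifted_composition(base: np.ndarray, shifts: np.ndarray,
                         exact: bool = True) -> np.ndarray:
    """Apply per-feature logit shifts to a composition.

    With ``exact=True`` (injected effects) each shifted feature takes
    exactly expit(logit(p) + shift) — so its realised log-odds-ratio
    equals the injected value — and only the unshifted remainder is
    renormalised.  With ``exact=False`` (kitten random intercept, which
    touches every feature) all features are shifted and the whole vector
    renormalised.
    """
    if not np.any(shifts):
        return base
    p = np.clip(base, 1e-12, 1 - 1e-12)
    if not exact:
        q = expit(logit(p) + shifts)
        return q / q.sum()
    out = base.copy()
    hit = shifts != 0
    out[hit] = expit(logit(p[hit]) + shifts[hit])
    mass_hit = out[hit].sum()
    mass_rest = base[~hit].sum()
    if mass_hit >= 1.0 or mass_rest <= 0:
        # shifted features swallow everything; fall back to global rescale
        return out / out.sum()
    out[~hit] = base[~hit] * (1.0 - mass_hit) / mass_rest
    return out


def generate_counts(
    design: StudyDesign,
    eff: EffectSpec,
    seed: int | None = None,
) -> tuple[FeatureTable, FeatureTable, dict[str, frozenset]]:
    """Draw genus counts, KO counts and gene-presence sets for a design.

    Per sample: the age-specific mean composition is shifted on the logit
    scale by any injected age/sex/neuter effects and by the kitten's
    random intercept, a composition is drawn from Dirichlet(theta * mean),
    and counts from Multinomial(denominator, composition) — so column sums
    equal the design denominators exactly.  KO counts redistribute the
    genus composition through fixed genus-specific KO profiles; each genus
    carries a private pool of gene ids whose union over the genera present
    forms the sample's gene set.
    """
    root = eff.seed if seed is None else seed
    genera = list(eff.genus_means.index)
    n_g = len(genera)
    ages = list(eff.genus_means.columns)
    g_index = {g: i for i, g in enumerate(genera)}

    kittens = sorted(design.table["kitten_id"].unique())
    rng_k = np.random.default_rng(root + _OFF_KITTEN)
    kitten_eps = {k: rng_k.normal(0.0, eff.kitten_sd, n_g) for k in kittens}

    # fixed genus -> KO profile (rows sum to 1)
    rng_p = np.random.default_rng(root + _OFF_KO_PROFILE)
    n_ko = eff.n_ko
    profile = rng_p.gamma(1.0, size=(n_g, n_ko)) * (
        rng_p.random((n_g, n_ko)) < eff.ko_density)
    home = rng_p.integers(0, n_g, size=n_ko)            # every KO reachable
    profile[home, np.arange(n_ko)] += rng_p.gamma(1.0, size=n_ko)
    empty = profile.sum(axis=1) == 0                    # genus hit no KO
    profile[empty] = 1.0 / n_ko
    profile /= profile.sum(axis=1, keepdims=True)
    ko_ids = [f"K{i + 1:05d}" for i in range(n_ko)]

    # genus-private gene pools
    rng_g = np.random.default_rng(root + _OFF_GENES)
    pools = {g: frozenset(f"{g}|g{j + 1}"
                          for j in range(5 + rng_g.poisson(eff.genes_per_genus)))
             for g in genera}

    rng_c = np.random.default_rng(root + _OFF_COMP)
    rng_ko = np.random.default_rng(root + _OFF_KO_COUNTS)

    age_pos = {a: i for i, a in enumerate(ages)}
    genus_cols, ko_cols, gene_sets = {}, {}, {}
    ko_shift_ids = list(eff.ko_age_log_or)
    for row in design.table.itertuples(index=False):
        base = eff.genus_means[row.age_week].to_numpy(copy=True)
        shifts = np.zeros(n_g)
        apos = age_pos[row.age_week]
        for g, (b30, b42) in eff.age_log_or.items():
            shifts[g_index[g]] += (0.0, b30, b42)[apos]
        if row.sex == "M":
            for g, b in eff.sex_log_or.items():
                shifts[g_index[g]] += b
        if row.neuter_group == "CN":
            for g, b in eff.neuter_log_or.items():
                shifts[g_index[g]] += b
        mean = _shifted_composition(base, shifts, exact=True)
        mean = _shifted_composition(mean, kitten_eps[row.kitten_id], exact=False)
        comp = rng_c.dirichlet(eff.theta * mean)
        counts = rng_c.multinomial(row.denominator, comp)
        genus_cols[row.sample_id] = counts

        ko_comp = comp @ profile
        if ko_shift_ids:
            kshift = np.zeros(n_ko)
            for kid, (b30, b42) in eff.ko_age_log_or.items():
                kshift[ko_ids.index(kid)] += (0.0, b30, b42)[apos]
            ko_comp = _shifted_composition(ko_comp / ko_comp.sum(), kshift)
        ko_cols[row.sample_id] = rng_ko.multinomial(row.denominator,
                                                    ko_comp / ko_comp.sum())
        present = [g for g, c in zip(genera, counts) if c > 0]
        gene_sets[row.sample_id] = frozenset().union(*(pools[g] for g in present)) \
            if present else frozenset()

    genus_t = FeatureTable("genus", pd.DataFrame(
        genus_cols, index=pd.Index(genera, name="feature_id")), "counts")
    ko_t = FeatureTable("KO", pd.DataFrame(
        ko_cols, index=pd.Index(ko_ids, name="feature_id")), "counts")
    return genus_t, ko_t, gene_sets


def generate_kegg_hierarchy(
    n_ko: int = 400,
    n_pathway: int = 60,
    mean_multiplicity: float = 1.5,
    n_group: int | None = None,
    n_supergroup: int | None = None,
    seed: int = 0,
) -> KeggHierarchy:
    """Random KO -> pathway -> group -> supergroup hierarchy.

    Each KO maps to ``1 + Poisson(mean_multiplicity - 1)`` distinct
    pathways (capped at ``n_pathway``), so the mean number of pathways per
    KO targets ``mean_multiplicity``; every pathway receives at least one
    KO.  Deterministic given seed.
    """
    if n_ko <= 0 or n_pathway <= 0:
        raise ValueError("n_ko and n_pathway must be positive")
    if mean_multiplicity < 1:
        raise ValueError("mean_multiplicity must be >= 1")
    rng = np.random.default_rng(seed + _OFF_HIERARCHY)
    n_group = n_group or max(1, n_pathway // 6)
    n_supergroup = n_supergroup or max(1, n_group // 3)

    pw_ids = [f"pw{i + 1:03d}" for i in range(n_pathway)]
    grp_ids = [f"grp{i + 1:02d}" for i in range(n_group)]
    sg_ids = [f"sg{i + 1:02d}" for i in range(n_supergroup)]
    ko_ids = [f"K{i + 1:05d}" for i in range(n_ko)]

    ko_to_pathways = {}
    for ko in ko_ids:
        mult = min(n_pathway, 1 + rng.poisson(mean_multiplicity - 1.0))
        ko_to_pathways[ko] = frozenset(
            pw_ids[j] for j in rng.choice(n_pathway, size=mult, replace=False))
    covered = frozenset().union(*ko_to_pathways.values())
    for pw in pw_ids:
        if pw not in covered:
            ko = ko_ids[int(rng.integers(0, n_ko))]
            ko_to_pathways[ko] = ko_to_pathways[ko] | {pw}

    pathway_to_group = {pw: grp_ids[int(rng.integers(0, n_group))] for pw in pw_ids}
    group_to_supergroup = {g: sg_ids[int(rng.integers(0, n_supergroup))]
                           for g in grp_ids}
    return KeggHierarchy(ko_to_pathways, pathway_to_group, group_to_supergroup)


def small_effect_spec(
    n_genera: int = 10,
    flat_ages: bool = True,
    age_log_or: Mapping[str, tuple[float, float]] | None = None,
    baseline: Mapping[str, float] | None = None,
    theta: float = 50.0,
    kitten_sd: float = 0.3,
    n_ko: int = 8,
    seed: int = 0,
) -> EffectSpec:
    """Scaled-down effect spec for simulation studies.

    Takes the ``n_genera`` most abundant calibrated genera (renormalised);
    with ``flat_ages=True`` the week-18 composition is used at every age,
    so any age signal comes solely from ``age_log_or`` — the configuration
    used for null-calibration and parameter-recovery studies.
    ``baseline`` overrides individual genus baseline proportions (the
    remainder is rescaled), e.g. to place a focal feature at 5 %.
    """
    full = default_effect_spec(seed=seed).genus_means
    top = full[full.columns[0]].sort_values(ascending=False).index[:n_genera]
    means = full.loc[top].copy()
    if flat_ages:
        for c in means.columns:
            means[c] = means[means.columns[0]]
    means = means / means.sum(axis=0)
    if baseline:
        for c in means.columns:
            col = means[c].copy()
            fixed = sum(baseline.values())
            if fixed >= 1.0:
                raise ValueError("baseline overrides must sum to < 1")
            others = [g for g in col.index if g not in baseline]
            rest = col[others].sum()
            for g, v in baseline.items():
                col[g] = v
            col[others] = col[others] * (1.0 - fixed) / rest
            means[c] = col
    return EffectSpec(genus_means=means, theta=theta, kitten_sd=kitten_sd,
                      age_log_or=dict(age_log_or or {}), n_ko=n_ko, seed=seed)


# ---------------------------------------------------------------------------
# one-call cohort

@dataclass
class SimulatedCohort:
    design: StudyDesign
    genus_counts: FeatureTable
    ko_counts: FeatureTable
    gene_sets: dict[str, frozenset]
    hierarchy: KeggHierarchy
    truth: dict


def simulate_cohort(seed: int = 0,
                    cohort: CohortSpec | None = None,
                    effects: EffectSpec | None = None,
                    n_pathway: int = 60) -> SimulatedCohort:
    """Generate design + counts + hierarchy in one call (the default cohort)."""
    cohort = cohort if cohort is not None else CohortSpec(seed=seed)
    effects = effects if effects is not None else default_effect_spec(seed=seed)
    design = generate_design(cohort)
    genus_t, ko_t, gene_sets = generate_counts(design, effects, seed=seed)
    hier = generate_kegg_hierarchy(n_ko=effects.n_ko, n_pathway=n_pathway, seed=seed)
    truth = {
        "seed": seed,
        "theta": effects.theta,
        "kitten_sd": effects.kitten_sd,
        "age_log_or": {k: list(v) for k, v in effects.age_log_or.items()},
        "sex_log_or": dict(effects.sex_log_or),
        "neuter_log_or": dict(effects.neuter_log_or),
        "n_samples": design.n_samples,
    }
    return SimulatedCohort(design, genus_t, ko_t, gene_sets, hier, truth)


def write_cohort(c: SimulatedCohort, outdir: str | Path,
                 header_comment: str | None = None) -> None:
    """Write the cohort as the package's standard TSVs plus a truth sidecar."""
    from .tables import write_design, write_feature_table, write_hierarchy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_design(c.design, outdir / "design.tsv", header_comment)
    write_feature_table(c.genus_counts, outdir / "genus_counts.tsv", header_comment)
    write_feature_table(c.ko_counts, outdir / "ko_counts.tsv", header_comment)
    write_hierarchy(c.hierarchy, outdir / "hierarchy.tsv")
    genes = {s: sorted(g) for s, g in c.gene_sets.items()}
    (outdir / "gene_sets.json").write_text(json.dumps(genes))
    (outdir / "truth.json").write_text(json.dumps(c.truth, indent=2))
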