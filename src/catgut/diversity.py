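"""Shannon diversity, replicate rarefaction, gene richness and trend tests.

Richness and diversity of each faecal sample are summarised as the
Shannon index H' = -sum p_i ln p_i (natural log) of species/genus
proportions, replicate subsampled rarefaction curves (subsampling reads
without replacement at a fixed depth schedule), and the number of unique
protein-coding genes.  Longitudinal trends are tested with linear mixed
models (kitten as random intercept; age, sex, neuter group and their
interactions as candidate categorical fixed effects) with backward
elimination at p >= 0.05 and Tukey-adjusted pairwise age comparisons.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, StudyDesign

__all__ = [
    "FULL_DEPTH_SCHEDULE",
    "shannon_index",
    "shannon_per_sample",
    "scaled_depth_schedule",
    "rarefy_richness",
    "rarefaction_table",
    "gene_richness",
    "fit_diversity_trend",
    "fit_rarefaction_trend",
]

log = logging.getLogger(__name__)

#: full-scale subsampling depth schedule (reads); desk runs rescale it
#: proportionally to each sample's read total (13 depths preserved)
FULL_DEPTH_SCHEDULE = (
    10_000, 20_000, 50_000, 100_000, 250_000, 500_000,
    1_000_000, 2_000_000, 4_000_000, 6_000_000, 8_000_000,
    10_000_000, 20_000_000,
)
_FULL_MAX = FULL_DEPTH_SCHEDULE[-1]


def shannon_index(p: Sequence[float]) -> float:
    """Shannon diversity H' (nats) of a proportion vector.

    Zero entries contribute nothing (0 ln 0 = 0).  The vector must be
    non-negative and sum to 1 within 1e-9; an all-zero vector is an error.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0 or not p.any():
        raise ValueError("all-zero abundance vector has no Shannon index")
    if (p < 0).any():
        raise ValueError("negative proportions")
    s = p.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {s:.6g}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_per_sample(t: FeatureTable) -> pd.Series:
    """Shannon index of every sample column (counts are normalised first)."""
    out = {}
    for s in t.sample_ids:
        col = t.data[s].to_numpy(dtype=float)
        tot = col.sum()
        if tot == 0:
            raise ValueError(f"sample {s!r} has no reads")
        out[s] = shannon_index(col / tot)
    return pd.Series(out, name="shannon")


def scaled_depth_schedule(total_reads: int,
                          full_schedule: Sequence[int] = FULL_DEPTH_SCHEDULE,
                          ) -> list[int]:
    """The 13-depth schedule rescaled so its top depth equals ``total_reads``."""
    return [max(1, round(d * total_reads / _FULL_MAX)) for d in full_schedule]


def rarefy_richness(counts: Sequence[int], depths: Sequence[int],
                    replicates: int = 10,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Replicate subsampled richness of one sample.

    Draws ``replicates`` independent subsamples without replacement from
    the read pool at each depth (multivariate hypergeometric) and counts
    the taxa observed.  Depths exceeding the read total are skipped with
    a warning; non-integer depths are an error.
    """
    counts = np.asarray(counts)
    if counts.dtype.kind not in "iu":
        if not np.all(np.asarray(counts) % 1 == 0):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    total = int(counts.sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for d in depths:
        if not float(d).is_integer():
            raise ValueError(f"non-integer depth {d!r}")
        d = int(d)
        if d > total:
            log.warning("depth %d exceeds read total %d; skipped", d, total)
            continue
        if d == total:
            rich = int((counts > 0).sum())
            rows.extend((d, r + 1, rich) for r in range(replicates))
            continue
        for r in range(replicates):
            sub = rng.multivariate_hypergeometric(counts, d)
            rows.append((d, r + 1, int((sub > 0).sum())))
    return pd.DataFrame(rows, columns=["depth", "replicate", "richness"])


def rarefaction_table(t: FeatureTable, depths: str | Sequence[int] = "scaled",
                      replicates: int = 10, seed: int = 0) -> pd.DataFrame:
    """Rarefaction rows (sample_id, depth, replicate, richness) for all samples.

    ``depths="scaled"`` rescales the 13-depth schedule per sample so the
    deepest subsample equals the sample's read total (every sample then
    contributes 13 x replicates rows); an explicit depth list is used as
    given, skipping depths beyond a sample's total.
    """
    if t.value_kind != "counts":
        raise ValueError("rarefaction requires a counts table")
    rng = np.random.default_rng(seed)
    frames = []
    for s in t.sample_ids:
        col = t.data[s].to_numpy()
        dl = scaled_depth_schedule(int(col.sum())) if isinstance(depths, str) else depths
        sub = rarefy_richness(col, dl, replicates, rng)
        sub.insert(0, "sample_id", s)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def gene_richness(gene_sets: Mapping[str, frozenset],
                  design: StudyDesign | None = None,
                  ) -> tuple[pd.Series, pd.Series | None]:
    """Unique-gene counts per sample and, given a design, per sampling age.

    The per-age count is the size of the union of gene sets over that
    age's samples.
    """
    per_sample = pd.Series({s: len(g) for s, g in gene_sets.items()},
                           name="n_genes")
    if design is None:
        return per_sample, None
    per_age = {}
    for age in design.ages:
        samples = [s for s in design.samples_at_age(age) if s in gene_sets]
        union: frozenset = frozenset()
        for s in samples:
            union = union | gene_sets[s]
        per_age[age] = len(union)
    return per_sample, pd.Series(per_age, name="n_genes")


# ---------------------------------------------------------------------------
# longitudinal trend testing (linear mixed models)

_MAINS = ("C(age_week)", "C(sex)", "C(neuter_group)")


def _candidate_terms() -> list[str]:
    m = list(_MAINS)
    two = [f"{a}:{b}" for i, a in enumerate(m) for b in m[i + 1:]]
    return m + two + [":".join(m)]


def _term_order(term: str) -> int:
    return term.count(":") + 1


def _contains(high: str, low: str) -> bool:
    return set(low.split(":")) < set(high.split(":"))


def _check_aliasing(df: pd.DataFrame, terms: Sequence[str]) -> None:
    import patsy

    X = patsy.dmatrix("1 + " + " + ".join(terms), df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # find the first term whose columns add no rank
        cols_so_far = X[["Intercept"]].to_numpy()
        di = X.design_info
        for term in di.term_names[1:]:
            idx = di.term_name_slices[term]
            cand = np.hstack([cols_so_far, X.iloc[:, idx].to_numpy()])
            if np.linalg.matrix_rank(cand) < cols_so_far.shape[1] + (idx.stop - idx.start):
                raise ValueError(f"singular design: term {term!r} is aliased")
            cols_so_far = cand


def fit_diversity_trend(values: pd.Series, design: StudyDesign,
                        alpha_elim: float = 0.05) -> dict:
    """Backward-eliminated linear mixed model for a per-sample scalar.

    Fits ``value ~ age * sex * neuter`` (categorical) with a kitten
    random intercept by maximum likelihood, drops non-significant fixed
    effects (p >= ``alpha_elim``; highest-order interactions first,
    largest p first; a main effect is never dropped while a retained
    interaction contains it) using likelihood-ratio tests, then reports
    Tukey-HSD-adjusted pairwise age comparisons from the final model.

    Returns a dict with keys ``final_terms``, ``dropped`` (term, p, order
    of removal), ``age_pairwise`` (per pair: estimate, se, p_tukey,
    significant at family-wise 5%), and ``age_significant``.
    """
    import statsmodels.formula.api as smf

    meta = design.indexed()
    if len(set(meta["age_week"])) < 2:
        raise ValueError("need >= 2 ages for a trend test")
    df = meta.copy()
    df["value"] = values.reindex(df.index)
    if df["value"].isna().any():
        missing = df.index[df["value"].isna()][0]
        raise ValueError(f"no value for sample {missing!r}")

    ages = sorted(df["age_week"].unique())
    pairs = [(a, b) for i, a in enumerate(ages) for b in ages[i + 1:]]
    if float(np.var(df["value"].to_numpy())) == 0.0:
        return {
            "final_terms": [], "dropped": [], "age_significant": False,
            "age_pairwise": {f"{a}-{b}": {"estimate": 0.0, "se": 0.0,
                                          "p_tukey": 1.0, "significant": False}
                             for a, b in pairs},
            "note": "constant response; no model fitted",
        }

    terms = _candidate_terms()
    _check_aliasing(df, terms)

    def fit(term_list):
        import warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        formula = "value ~ " + (" + ".join(term_list) if term_list else "1")
        with warnings.catch_warnings():
            # saturated interaction models routinely sit on the variance
            # boundary during elimination; the LRT chain tolerates that
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            return smf.mixedlm(formula, df, groups=df["kitten_id"]).fit(reml=False)

    current = list(terms)
    res = fit(current)
    dropped = []
    while True:
        droppable = [t for t in current
                     if not any(_contains(h, t) for h in current if h != t)]
        if not droppable:
            break
        tested = []
        for t in droppable:
            reduced = [x for x in current if x != t]
            r2 = fit(reduced)
            lr = 2.0 * (res.llf - r2.llf)
            dof = res.df_modelwc - r2.df_modelwc
            p = float(stats.chi2.sf(max(lr, 0.0), max(int(dof), 1)))
            tested.append((p, t, r2))
        tested.sort(key=lambda x: (-x[0], x[1]))
        p, t, r2 = tested[0]
        if p < alpha_elim:
            break
        current.remove(t)
        dropped.append({"term": t, "p": p})
        res = fit(current) if current else fit([])

    # Tukey-adjusted pairwise age comparisons from the final model
    import patsy

    age_term_present = any("age_week" in t for t in current)
    formula_rhs = "1 + " + " + ".join(current) if current else "1"
    X = patsy.dmatrix(formula_rhs, df, return_type="dataframe")
    beta = res.fe_params.to_numpy()
    V = res.cov_params().iloc[:len(beta), :len(beta)].to_numpy()
    n = len(df)
    dof = max(n - X.shape[1] - 1, 1)
    k = len(ages)

    def lsmean_vec(age):
        # average design row over the observed covariate grid at this age
        df_a = df.copy()
        df_a["age_week"] = age
        Xa = patsy.build_design_matrices([X.design_info], df_a,
                                         return_type="dataframe")[0]
        return Xa.to_numpy().mean(axis=0)

    means = {a: lsmean_vec(a) for a in ages}
    age_pairwise = {}
    for a, b in pairs:
        c = means[b] - means[a]
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        if se == 0.0 or not age_term_present:
            p_t = 1.0
            est = est if age_term_present else 0.0
        else:
            q = abs(est / se) * np.sqrt(2.0)
            p_t = float(stats.studentized_range.sf(q, k, dof))
        age_pairwise[f"{a}-{b}"] = {
            "estimate": est, "se": se, "p_tukey": p_t,
            "significant": bool(p_t < 0.05),
        }
    return {
        "final_terms": current,
        "dropped": dropped,
        "age_significant": age_term_present,
        "age_pairwise": age_pairwise,
        "n_obs": n,
    }


def fit_rarefaction_trend(rtable: pd.DataFrame, design: StudyDesign,
                          alpha_elim: float = 0.05) -> dict:
    """Trend test on rarefied richness.

    Summarises each sample by its mean replicate richness at the sample's
    deepest subsampling depth and delegates to
    :func:`fit_diversity_trend`.  The full depth-within-age-within-kitten
    nesting with depth-variability weights is deliberately approximated
    by the kitten-level random intercept; the report records this.
    """
    deepest = rtable.loc[rtable.groupby("sample_id")["depth"].idxmax(),
                         ["sample_id", "depth"]]
    top = rtable.merge(deepest, on=["sample_id", "depth"])
    values = top.groupby("sample_id")["richness"].mean()
    rep = fit_diversity_trend(values, design, alpha_elim)
    rep["note"] = ("richness averaged over replicates at each sample's deepest "
                   "depth; depth nesting approximated by kitten random intercept")
    return rep
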