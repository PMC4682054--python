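"""Directional permutation pathway enrichment.

Given the set of analysed KOs (the universe) and the subset whose odds
consistently increase (or decrease) with age, a pathway is enriched when
it contains more of those directional KOs than random subsets of the
same size would place in it.  The permutation p-value is the fraction of
``n_perm`` random subsets (drawn without replacement from the universe)
whose per-pathway count reaches the observed count — exactly a Monte
Carlo estimate of the hypergeometric tail, which is also computed in
closed form as a cross-check.  Family-wise error over the pathways
tested is controlled by a Sidak critical value.

With 1,000 permutations the only achievable p below a Sidak cutoff of
~3e-4 is exactly 0; the run report surfaces this granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import sidak_threshold
from .tables import KeggHierarchy

__all__ = [
    "hypergeom_tail",
    "permutation_enrichment",
    "select_enriched",
    "enrich_directions",
]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: pathway size within the universe, n: subset
    size, k: observed directional KOs in the pathway.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def permutation_enrichment(
    universe,
    subset_size: int,
    per_pathway_observed: dict[str, int],
    h: KeggHierarchy,
    n_perm: int = 1000,
    seed: int = 0,
    bias_corrected: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for every pathway, one shared permutation stream.

    Each of ``n_perm`` rounds draws ``subset_size`` KOs from the
    universe without replacement and counts them per pathway; a
    pathway's p is the fraction of rounds with count >= observed.
    ``bias_corrected`` uses (hits+1)/(n_perm+1) instead of hits/n_perm —
    off by default since the plain fraction is the percentage-of-subsets
    definition (and the corrected one can never reach a Sidak cutoff
    below 1/n_perm).  Deterministic given seed.
    """
    universe = sorted(set(universe))
    N = len(universe)
    if subset_size > N:
        raise ValueError(f"subset_size {subset_size} exceeds universe {N}")
    pw_members = h.pathway_to_kos()
    uni_index = {ko: i for i, ko in enumerate(universe)}
    pathways = sorted(p for p, m in pw_members.items()
                      if any(ko in uni_index for ko in m))
    M = np.zeros((len(pathways), N), dtype=bool)
    for i, p in enumerate(pathways):
        for ko in pw_members[p]:
            j = uni_index.get(ko)
            if j is not None:
                M[i, j] = True
    totals = M.sum(axis=1)
    observed = np.array([per_pathway_observed.get(p, 0) for p in pathways])
    if (observed > totals).any():
        bad = pathways[int(np.argmax(observed > totals))]
        raise ValueError(f"observed count exceeds pathway size for {bad!r}")

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(pathways), dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.choice(N, size=subset_size, replace=False)
        counts = M[:, idx].sum(axis=1)
        hits += counts >= observed
    p_perm = ((hits + 1) / (n_perm + 1)) if bias_corrected else hits / n_perm
    p_exact = np.array([hypergeom_tail(N, int(K), subset_size, int(k))
                        for K, k in zip(totals, observed)])
    return pd.DataFrame({
        "pathway_id": pathways, "total": totals, "significant": observed,
        "p_perm": p_perm, "p_hypergeom": p_exact,
        "n_permutations": n_perm, "seed": seed,
    }).set_index("pathway_id")


def select_enriched(results: pd.DataFrame, alpha: float = 0.05,
                    m: int | None = None) -> pd.DataFrame:
    """Flag pathways with permutation p below the Sidak critical value."""
    m = m if m is not None else len(results)
    thr = sidak_threshold(alpha, m)
    out = results.copy()
    out["sidak_threshold"] = thr
    out["enriched"] = out["p_perm"] < thr
    return out


@dataclass
class DirectionalEnrichment:
    up: pd.DataFrame
    down: pd.DataFrame
    universe_size: int
    notes: list


def enrich_directions(
    universe,
    up_kos,
    down_kos,
    h: KeggHierarchy,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    universe_mode: str = "analysed",
) -> DirectionalEnrichment:
    """Run the up- and down-directional enrichment tests.

    Mixed-direction KOs are excluded from the directional subsets but —
    by default (``universe_mode="analysed"``) — not from the universe.
    ``universe_mode="directional"`` restricts the universe to up+down
    KOs instead.  The two directions use independent streams seeded from
    the root seed.
    """
    universe = set(universe)
    up_kos, down_kos = set(up_kos), set(down_kos)
    if up_kos & down_kos:
        raise ValueError("a KO cannot be both up and down")
    if universe_mode == "directional":
        universe = up_kos | down_kos
    elif universe_mode != "analysed":
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    if not (up_kos <= universe and down_kos <= universe):
        raise ValueError("directional subsets must lie within the universe")

    pw_members = h.pathway_to_kos()

    def observed_counts(subset):
        return {p: len(m & subset) for p, m in pw_members.items()}

    notes = []
    frames = {}
    for label, subset, offset in (("up", up_kos, 1), ("down", down_kos, 2)):
        res = permutation_enrichment(universe, len(subset),
                                     observed_counts(subset), h,
                                     n_perm=n_perm, seed=seed + offset)
        res = select_enriched(res, alpha=alpha)
        thr = float(res["sidak_threshold"].iloc[0]) if len(res) else np.nan
        if len(res) and thr < 1.0 / n_perm:
            notes.append(
                f"{label}: Sidak cutoff {thr:.2e} is below 1/{n_perm}; "
                "only permutation p = 0 can be declared enriched")
        frames[label] = res
    return DirectionalEnrichment(frames["up"], frames["down"], len(universe), notes)
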