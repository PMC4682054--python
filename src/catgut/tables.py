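"""Core data model and I/O: feature tables, study design, KEGG-style hierarchy.

A :class:`FeatureTable` holds per-sample counts or relative abundances of
features at one annotation level (phylum ... species for taxonomy, KO /
pathway / pathway group for function).  A :class:`StudyDesign` carries the
per-sample covariates of the longitudinal kitten cohort (kitten, litter,
sex, neuter group, sampling age) plus the per-sample annotated-read
denominator used to form proportions.  A :class:`KeggHierarchy` maps
ortholog groups (KOs) into biochemical pathways (many-to-many) and
pathways into pathway groups and supergroups (trees).

All files are tab-separated UTF-8 with "." decimals; feature tables are
features-in-rows.  Proportions live in [0, 1] internally; percentages
appear only in report helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "StudyDesign",
    "KeggHierarchy",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "read_hierarchy",
    "write_hierarchy",
    "to_relative_abundance",
    "aggregate_to_level",
    "summarize_abundant_features",
]

LEVELS = (
    "superkingdom", "phylum", "class", "order", "family", "genus", "species",
    "KO", "pathway", "pathway_group", "supergroup",
)

_PROP_TOL = 1e-9


@dataclass
class FeatureTable:
    """Feature-by-sample abundance table tied to one annotation level.

    Parameters
    ----------
    level
        Annotation level label (e.g. ``"genus"``, ``"KO"``).
    data
        DataFrame with features in rows, samples in columns; non-negative.
    value_kind
        ``"counts"`` or ``"proportions"``.
    """

    level: str
    data: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "proportions"):
            raise ValueError(f"value_kind must be counts|proportions, got {self.value_kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.value_kind == "proportions" and vals.size:
            colsums = vals.sum(axis=0)
            bad = np.nonzero(colsums > 1 + _PROP_TOL)[0]
            if bad.size:
                raise ValueError(
                    f"proportions in sample {self.data.columns[bad[0]]!r} "
                    f"sum to {colsums[bad[0]]:.6g} > 1"
                )

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.level, self.data[list(sample_ids)], self.value_kind)


DESIGN_COLUMNS = [
    "sample_id", "kitten_id", "litter_id", "sex", "neuter_group",
    "age_week", "denominator",
]


@dataclass
class StudyDesign:
    """Per-sample covariates and denominators of the longitudinal cohort.

    One row per faecal sample: kitten, litter, sex (F|M), neuter group
    (EN early / CN conventional), sampling age in weeks, and the total
    number of annotated reads used as the binomial denominator.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        pairs = t[["kitten_id", "age_week"]]
        if pairs.duplicated().any():
            raise ValueError("a (kitten_id, age_week) pair appears more than once")
        for col in ("sex", "neuter_group"):
            per_kitten = t.groupby("kitten_id")[col].nunique()
            if (per_kitten > 1).any():
                k = per_kitten[per_kitten > 1].index[0]
                raise ValueError(f"{col} not constant within kitten {k!r}")
        bad = ~t["sex"].isin(["F", "M"])
        if bad.any():
            raise ValueError(f"invalid sex value {t.loc[bad, 'sex'].iloc[0]!r}")
        bad = ~t["neuter_group"].isin(["EN", "CN"])
        if bad.any():
            raise ValueError(f"invalid neuter_group {t.loc[bad, 'neuter_group'].iloc[0]!r}")
        if (t["denominator"] <= 0).any():
            raise ValueError("denominator must be > 0 for every sample")

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    @property
    def ages(self) -> list:
        return sorted(self.table["age_week"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def denominators(self) -> pd.Series:
        return self.table.set_index("sample_id")["denominator"]

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("sample_id")

    def samples_at_age(self, age_week: int) -> list:
        t = self.table
        return list(t.loc[t["age_week"] == age_week, "sample_id"])


@dataclass
class KeggHierarchy:
    """KO -> pathway (many-to-many) plus pathway -> group -> supergroup maps."""

    ko_to_pathways: dict[str, frozenset]
    pathway_to_group: dict[str, str]
    group_to_supergroup: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ko_to_pathways = {k: frozenset(v) for k, v in self.ko_to_pathways.items()}
        for ko, pws in self.ko_to_pathways.items():
            for pw in pws:
                if pw not in self.pathway_to_group:
                    raise ValueError(f"pathway {pw!r} (from KO {ko!r}) has no pathway group")
        for pw, grp in self.pathway_to_group.items():
            if grp not in self.group_to_supergroup:
                raise ValueError(f"group {grp!r} (from pathway {pw!r}) has no supergroup")

    @property
    def pathways(self) -> list:
        return sorted(self.pathway_to_group)

    @property
    def kos(self) -> list:
        return sorted(self.ko_to_pathways)

    def pathway_to_kos(self) -> dict[str, frozenset]:
        """Invert the KO -> pathway map."""
        out: dict[str, set] = {p: set() for p in self.pathway_to_group}
        for ko, pws in self.ko_to_pathways.items():
            for pw in pws:
                out[pw].add(ko)
        return {p: frozenset(s) for p, s in out.items()}

    def mean_multiplicity(self) -> float:
        """Mean number of pathways per mapped KO."""
        sizes = [len(v) for v in self.ko_to_pathways.values() if v]
        return float(np.mean(sizes)) if sizes else float("nan")


# ---------------------------------------------------------------------------
# I/O

def read_feature_table(path: Union[str, Path], level: str) -> FeatureTable:
    """Read a features-in-rows TSV (header = sample ids, first column = feature id).

    Raises a hard error naming the offender for duplicate ids and for
    negative or non-numeric cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"no features in {path}")
    if df.shape[1] == 0:
        raise ValueError(f"no samples in {path}")
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(df.columns):
            conv = pd.to_numeric(df[col], errors="coerce")
            if conv.isna().any() and not df[col].isna().any():
                row = conv.index[conv.isna() & ~df[col].isna()][0]
                raise ValueError(
                    f"non-numeric value at feature {row!r}, sample {col!r} in {path}"
                ) from None
        raise
    num.index = num.index.astype(str)
    num.index.name = "feature_id"
    # integer-valued input stays integer counts
    if (num.to_numpy() % 1 == 0).all():
        kind = "counts"
        num = num.astype(np.int64)
    else:
        kind = "proportions"
    return FeatureTable(level=level, data=num, value_kind=kind)


def write_feature_table(t: FeatureTable, path: Union[str, Path], header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = t.data.copy()
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t")


def read_design(path: Union[str, Path]) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "kitten_id": str, "litter_id": str})
    return StudyDesign(df)


def write_design(d: StudyDesign, path: Union[str, Path], header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        d.table.to_csv(fh, sep="\t", index=False)


def read_hierarchy(path: Union[str, Path]) -> KeggHierarchy:
    """Read a hierarchy TSV with columns ko_id, pathway_id, group_id, supergroup_id.

    Repeated ko_id rows encode the many-to-many KO -> pathway relation.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    ko_to_pathways: dict[str, set] = {}
    pathway_to_group: dict[str, str] = {}
    group_to_supergroup: dict[str, str] = {}
    for row in df.itertuples(index=False):
        ko_to_pathways.setdefault(row.ko_id, set()).add(row.pathway_id)
        pathway_to_group[row.pathway_id] = row.group_id
        group_to_supergroup[row.group_id] = row.supergroup_id
    return KeggHierarchy(
        {k: frozenset(v) for k, v in ko_to_pathways.items()},
        pathway_to_group, group_to_supergroup,
    )


def write_hierarchy(h: KeggHierarchy, path: Union[str, Path]) -> None:
    rows = []
    for ko in sorted(h.ko_to_pathways):
        for pw in sorted(h.ko_to_pathways[ko]):
            grp = h.pathway_to_group[pw]
            rows.append((ko, pw, grp, h.group_to_supergroup[grp]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["ko_id", "pathway_id", "group_id", "supergroup_id"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transformations

def to_relative_abundance(
    t: FeatureTable,
    denominators: Union[str, Mapping, pd.Series] = "column_sum",
) -> FeatureTable:
    """Convert a counts table to per-sample relative abundances.

    ``denominators="column_sum"`` normalises each sample column to sum 1.
    An explicit per-sample mapping (e.g. total annotated reads) may leave
    column sums below 1 — the unannotated remainder is simply absent.
    """
    if t.value_kind != "counts":
        raise ValueError("to_relative_abundance expects a counts table")
    if isinstance(denominators, str):
        if denominators != "column_sum":
            raise ValueError(f"unknown denominator mode {denominators!r}")
        denom = t.data.sum(axis=0).astype(float)
    else:
        denom = pd.Series(denominators, dtype=float).reindex(t.data.columns)
        if denom.isna().any():
            missing = denom.index[denom.isna()][0]
            raise ValueError(f"no denominator for sample {missing!r}")
        colsum = t.data.sum(axis=0)
        short = denom.index[(denom + 1e-9) < colsum]
        if len(short):
            raise ValueError(
                f"denominator for sample {short[0]!r} is smaller than its column sum")
    if (denom == 0).any():
        z = denom.index[denom == 0][0]
        raise ValueError(f"zero denominator for sample {z!r}")
    prop = t.data.astype(float).div(denom, axis=1)
    return FeatureTable(level=t.level, data=prop, value_kind="proportions")


def aggregate_to_level(
    t: FeatureTable,
    mapping: Mapping[str, Union[str, Iterable[str]]],
    level: str = "aggregated",
    weight: str = "full",
    unmapped_label: str = "unmapped",
) -> FeatureTable:
    """Sum child features into parents (e.g. genus -> phylum, KO -> pathway).

    ``mapping`` values may be a single parent or an iterable of parents
    (the many-to-many KO -> pathway step).  With ``weight="full"`` a child's
    value is added in full to every parent it maps to, matching the KEGG
    convention — pathway columns of a proportions table may therefore sum
    to more than 1.  ``weight="split"`` divides by the multiplicity instead,
    conserving mass.  Children absent from the mapping are routed to
    ``unmapped_label``.
    """
    if weight not in ("full", "split"):
        raise ValueError("weight must be 'full' or 'split'")
    parents: dict[str, np.ndarray] = {}
    values = t.data.to_numpy(dtype=float)
    missing = []
    for i, feat in enumerate(t.data.index):
        targets = mapping.get(feat)
        if targets is None:
            missing.append(feat)
            targets = [unmapped_label]
        elif isinstance(targets, str):
            targets = [targets]
        else:
            targets = sorted(set(targets))
        w = 1.0 / len(targets) if weight == "split" else 1.0
        for p in targets:
            if p in parents:
                parents[p] = parents[p] + values[i] * w
            else:
                parents[p] = values[i] * w
    order = sorted(parents)
    out = pd.DataFrame(
        np.vstack([parents[p] for p in order]) if order else np.empty((0, t.n_samples)),
        index=pd.Index(order, name="feature_id"), columns=t.data.columns,
    )
    kind = t.value_kind
    if kind == "proportions" and weight == "full":
        # many-to-many full weights can push column sums past 1; keep the
        # numbers but relax the container to plain counts-of-proportion mass
        colsums = out.sum(axis=0)
        if (colsums > 1 + _PROP_TOL).any():
            kind = "counts"
    if kind == "counts" and (out.to_numpy() % 1 == 0).all():
        out = out.astype(np.int64)
    result = FeatureTable(level=level, data=out, value_kind=kind)
    result.unmapped_features = missing  # type: ignore[attr-defined]
    return result


def summarize_abundant_features(
    t: FeatureTable,
    design: StudyDesign,
    threshold: float = 0.003,
    parent_map: Mapping[str, str] | None = None,
    parent_table: FeatureTable | None = None,
) -> pd.DataFrame:
    """Per-age arithmetic-mean abundance of features reaching ``threshold``.

    A feature is retained when its arithmetic-mean relative abundance over
    the samples of at least one sampling age is >= ``threshold``.  When a
    ``parent_map`` (e.g. genus -> phylum) and a parent-level proportions
    table are supplied, per-parent mean rows and a ``Total (parents)`` row
    summing the displayed parent means are appended; parent means cover all
    children of the parent, not only the displayed ones.

    Returns a DataFrame indexed by feature with one column per age holding
    mean proportions, plus ``role`` (feature|parent|total) and ``parent``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if t.value_kind != "proportions":
        raise ValueError("summarize_abundant_features expects proportions")
    ages = design.ages
    means = pd.DataFrame(
        {age: t.data[design.samples_at_age(age)].mean(axis=1) for age in ages})
    keep = means.ge(threshold).any(axis=1)
    feats = means.loc[keep].sort_values(by=ages[0], ascending=False)
    rows = []
    for fid, row in feats.iterrows():
        rows.append({"feature_id": fid, "role": "feature",
                     "parent": parent_map.get(fid, "") if parent_map else "",
                     **{age: row[age] for age in ages}})
    if parent_table is not None and parent_map is not None:
        pmeans = pd.DataFrame(
            {age: parent_table.data[design.samples_at_age(age)].mean(axis=1)
             for age in ages})
        shown_parents = sorted({parent_map[f] for f in feats.index if f in parent_map})
        for p in shown_parents:
            if p in pmeans.index:
                rows.append({"feature_id": p, "role": "parent", "parent": "",
                             **{age: pmeans.loc[p, age] for age in ages}})
        total = pmeans.loc[[p for p in shown_parents if p in pmeans.index]].sum(axis=0)
        rows.append({"feature_id": "Total (parents)", "role": "total", "parent": "",
                     **{age: total[age] for age in ages}})
    rows.append({"feature_id": "Total (features)", "role": "total_features", "parent": "",
                 **{age: feats[age].sum() for age in ages}})
    return pd.DataFrame(rows).set_index("feature_id")


def round_percent(p: float, decimals: int = 1) -> float:
    """Half-up rounding of a proportion expressed in percent space."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(p * 100.0)).quantize(q, rounding=ROUND_HALF_UP))
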