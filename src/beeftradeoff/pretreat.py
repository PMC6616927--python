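"""Pre-treatment: standardization and clustering of variables.

Dimension reduction proceeds variable-wise, not animal-wise: within each
parameter of interest, correlated variables are grouped by hierarchical
ascending clustering *of variables* around latent components.  Each cluster's
latent is the first principal component of its members, and the quality of a
partition is its homogeneity: the share of total variable variance captured
by the cluster latents,

    H(P) = 100 * sum_clusters lambda_1(R_C) / p        (percent),

with ``lambda_1(R_C)`` the leading eigenvalue of the members' correlation
matrix.  Merging always loses homogeneity, so the greedy agglomeration picks
at each step the merge with the smallest loss.  Clusters are then summarized
into a fixed indicator layout (24 indicators: 3 AP + 7 CP + 7 NQ + 7 OQ)
either by their latent, by one or more named representative members, or by
passing unclustered variables straight through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import HerdTable

__all__ = [
    "StandardizedTable",
    "ClusterSolution",
    "IndicatorTable",
    "standardize",
    "cluster_variables",
    "homogeneity",
    "summarize",
    "INDICATOR_LAYOUT",
    "pretreat_herd",
]


@dataclass
class StandardizedTable:
    """Column-wise z-scored table with the statistics needed to invert it."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def back_transform(self) -> pd.DataFrame:
        return self.values * self.sds + self.means

    def subset(self, columns: list[str]) -> "StandardizedTable":
        return StandardizedTable(
            self.values[columns], self.means[columns], self.sds[columns]
        )


def standardize(table: HerdTable | pd.DataFrame) -> StandardizedTable:
    """Center and reduce every column by its sample standard deviation (ddof=1)."""
    df = table.values if isinstance(table, HerdTable) else table
    means = df.mean()
    sds = df.std(ddof=1)
    bad = sds[(sds == 0) | sds.isna()]
    if len(bad):
        raise ValueError(f"zero-variance column(s): {list(bad.index)}")
    return StandardizedTable((df - means) / sds, means, sds)


def _leading_eig(R: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(R)
    return float(vals[-1]), vecs[:, -1]


@dataclass
class ClusterSolution:
    """A partition of variables with per-cluster latents and loadings.

    Cluster ids are 0..k-1, ordered by each cluster's lowest variable index.
    The latent of a cluster is the first principal component of its members,
    standardized to unit variance and oriented to correlate positively with
    its highest-loading member.
    """

    membership: dict[str, int]
    latent: pd.DataFrame  # animals x clusters, columns "c0".."c{k-1}"
    loadings: pd.Series  # variable -> corr(variable, its cluster latent)
    eigenvalues: list[float]  # leading eigenvalue per cluster
    homogeneity_pct: float
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    def members(self, cluster: int) -> list[str]:
        return [v for v, c in self.membership.items() if c == cluster]

    def cluster_of(self, variable: str) -> int:
        return self.membership[variable]


def cluster_variables(sub: StandardizedTable, k: int) -> ClusterSolution:
    """Hierarchical ascending clustering of variables around latent components.

    Greedy agglomeration from singletons: at each step merge the pair of
    clusters whose union loses the least total homogeneity (sum over clusters
    of the leading eigenvalue of the member correlation matrix).  Ties are
    broken by lowest variable index, making the procedure deterministic for a
    given column order.  The cut at ``k`` is followed by a consolidation pass:
    variables are iteratively reassigned to the cluster latent they correlate
    most with (in squared correlation), which can only increase the
    homogeneity criterion and corrects greedy merge artefacts.
    """
    X = sub.values
    names = list(X.columns)
    p = len(names)
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range [1, {p}]")
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    R = np.atleast_2d(R)

    clusters: list[list[int]] = [[j] for j in range(p)]
    eigs: list[float] = [1.0] * p

    def merged_eig(a: list[int], b: list[int]) -> float:
        idx = a + b
        return _leading_eig(R[np.ix_(idx, idx)])[0]

    while len(clusters) > k:
        best = None  # (loss, min_idx_a, min_idx_b, ia, ib, new_eig)
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                e = merged_eig(clusters[ia], clusters[ib])
                loss = eigs[ia] + eigs[ib] - e
                key = (loss, min(clusters[ia]), min(clusters[ib]))
                if best is None or key < best[0]:
                    best = (key, ia, ib, e)
        _, ia, ib, e = best
        clusters[ia] = sorted(clusters[ia] + clusters[ib])
        eigs[ia] = e
        del clusters[ib], eigs[ib]

    # consolidation: move single variables between clusters while the total
    # homogeneity strictly increases (terminates: the criterion is bounded)
    while True:
        moved = False
        for j in range(p):
            cur = next(i for i, c in enumerate(clusters) if j in c)
            if len(clusters[cur]) == 1:
                continue  # never empty a cluster
            without = [x for x in clusters[cur] if x != j]
            eig_without = _leading_eig(R[np.ix_(without, without)])[0]
            best_gain, best_i, best_eig = 1e-12, None, None
            for i in range(len(clusters)):
                if i == cur:
                    continue
                with_j = sorted(clusters[i] + [j])
                eig_with = _leading_eig(R[np.ix_(with_j, with_j)])[0]
                gain = (eig_without + eig_with) - (eigs[cur] + eigs[i])
                if gain > best_gain:
                    best_gain, best_i, best_eig = gain, i, eig_with
            if best_i is not None:
                clusters[cur] = without
                eigs[cur] = eig_without
                clusters[best_i] = sorted(clusters[best_i] + [j])
                eigs[best_i] = best_eig
                moved = True
        if not moved:
            break

    order = np.argsort([min(c) for c in clusters])
    clusters = [clusters[i] for i in order]
    eigs = [eigs[i] for i in order]

    membership: dict[str, int] = {}
    lat_cols: dict[str, np.ndarray] = {}
    loadings: dict[str, float] = {}
    for cid, idx in enumerate(clusters):
        for j in idx:
            membership[names[j]] = cid
        Xc = X.iloc[:, idx].to_numpy()
        lam, v = _leading_eig(R[np.ix_(idx, idx)])
        scores = Xc @ v
        s = scores.std(ddof=1)
        scores = scores / s if s > 0 else scores
        # orient: positive correlation with the highest-|loading| member
        corr = np.array(
            [np.corrcoef(Xc[:, m], scores)[0, 1] if scores.std() > 0 else 0.0
             for m in range(len(idx))]
        )
        anchor = int(np.argmax(np.abs(corr)))
        if corr[anchor] < 0:
            scores, corr = -scores, -corr
        lat_cols[f"c{cid}"] = scores
        for m, j in enumerate(idx):
            loadings[names[j]] = float(corr[m])

    return ClusterSolution(
        membership=membership,
        latent=pd.DataFrame(lat_cols, index=X.index),
        loadings=pd.Series(loadings),
        eigenvalues=eigs,
        homogeneity_pct=100.0 * sum(eigs) / p,
        data=X,
    )


def homogeneity(sol: ClusterSolution, p: int | None = None) -> float:
    """Percent of variable variance captured by the cluster latents."""
    if p is None:
        p = len(sol.membership)
    return 100.0 * sum(sol.eigenvalues) / p


def summarize(
    sol: ClusterSolution,
    rules: dict[int, tuple],
    passthrough: list[tuple[pd.Series, str]] | None = None,
) -> pd.DataFrame:
    """Collapse clusters into named indicator columns (not yet re-standardized).

    ``rules`` maps a cluster id to either ``("latent", name)`` — emit the
    cluster's first-PC score — or ``("representative", [(member, name), ...])``
    — emit the named member variables themselves; clusters without a rule are
    dropped.  ``passthrough`` appends extra standardized columns unchanged.
    """
    cols: dict[str, pd.Series] = {}
    for cid, rule in rules.items():
        if cid < 0 or cid >= sol.k:
            raise ValueError(f"no cluster {cid} in solution with k={sol.k}")
        kind = rule[0]
        if kind == "latent":
            cols[rule[1]] = sol.latent[f"c{cid}"]
        elif kind == "representative":
            for member, name in rule[1]:
                if sol.membership.get(member) != cid:
                    raise ValueError(
                        f"representative {member!r} is not a member of cluster {cid}"
                    )
                cols[name] = sol.data[member]
        else:
            raise ValueError(f"unknown summary rule {kind!r}")
    for series, name in passthrough or []:
        cols[name] = series
    return pd.DataFrame(cols)


@dataclass
class IndicatorTable:
    """The standardized indicator layout the modeling stage consumes."""

    values: pd.DataFrame  # animals x indicators, standardized
    group_map: dict[str, str]  # indicator -> AP/CP/NQ/OQ
    summary_rule: dict[str, str]  # indicator -> latent/representative/passthrough

    @property
    def indicator_names(self) -> list[str]:
        return list(self.values.columns)

    def group_indicators(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.group_map[c] == group]


# The default indicator plan. Within each clustered group, "latent" indicators
# are identified by a seed variable: the indicator is the latent of whichever
# cluster contains that seed. "representative" indicators are the standardized
# variable itself (the rest of its cluster is absorbed/dropped), and
# "passthrough" variables never enter the clustering.
INDICATOR_LAYOUT: dict[str, dict] = {
    "AP": {
        "cluster": False,
        "passthrough": [("slaughter_weight", "slaughter weight"), ("adg", "ADG"), ("fcr", "FCR")],
    },
    "CP": {
        "cluster": True,
        "k": 6,
        "exclude": [],
        "representative": [("carcass_weight", "carcass weight"), ("ph_ultimate", "pH")],
        "latent": [
            ("conformation_score", "conformation"),
            ("lightness_L", "h*L*"),
            ("kidney_fat_kg", "fat development"),
            ("fat_proportion", "fat proportion"),
            ("a_star", "a*b*C*"),
        ],
        "passthrough": [],
    },
    "NQ": {
        "cluster": True,
        "k": 6,
        "exclude": ["lipid_content"],
        "representative": [("n6_n3_ratio", "n-6/n-3")],
        "latent": [
            ("long_fa_amount", "long FA"),
            ("c16_c18_ratio", "C16:0/C18:0"),
            ("pufa_mufa_ratio", "PUFA/MUFA"),
            ("cla_total", "CLA"),
            ("trans_fa_total", "trans FA"),
        ],
        "passthrough": [("lipid_content", "lipid content")],
    },
    "OQ": {
        "cluster": True,
        "k": 5,
        "exclude": ["tenderness", "juiciness"],
        "representative": [],
        "latent": [
            ("flavor_intensity", "flavor intensity"),
            ("bitter_flavor", "bitter"),
            ("rancid_flavor", "rancid fish"),
            ("fatty_flavor", "fatty vs metal"),
            ("blood_flavor", "blood acid"),
        ],
        "passthrough": [("tenderness", "tenderness"), ("juiciness", "juiciness")],
    },
}


def pretreat_herd(
    herd: HerdTable,
    layout: dict[str, dict] | None = None,
    cluster_counts: dict[str, int] | None = None,
) -> tuple[IndicatorTable, dict[str, ClusterSolution]]:
    """Standardize, cluster each group, and summarize into the indicator table.

    Returns the 24-indicator table (re-standardized) and the per-group cluster
    solutions.  ``cluster_counts`` overrides the per-group number of clusters.
    """
    layout = layout or INDICATOR_LAYOUT
    std = standardize(herd)
    solutions: dict[str, ClusterSolution] = {}
    cols: dict[str, pd.Series] = {}
    group_map: dict[str, str] = {}
    rule_map: dict[str, str] = {}

    for group in ("AP", "CP", "NQ", "OQ"):
        plan = layout[group]
        gcols = herd.group_columns(group)
        for var, name in plan.get("passthrough", []):
            cols[name] = std.values[var]
            group_map[name] = group
            rule_map[name] = "passthrough"
        if not plan.get("cluster", False):
            continue
        clustered = [c for c in gcols if c not in plan.get("exclude", [])]
        k = (cluster_counts or {}).get(group, plan["k"])
        sol = cluster_variables(std.subset(clustered), k)
        solutions[group] = sol

        rules: dict[int, tuple] = {}
        for var, name in plan.get("representative", []):
            cid = sol.cluster_of(var)
            rules.setdefault(cid, ("representative", []))
            if rules[cid][0] != "representative":
                warnings.warn(
                    f"cluster {cid} of {group} already summarized by a latent; "
                    f"emitting {var!r} as a representative as well"
                )
                rules[cid] = ("representative", [])
            rules[cid][1].append((var, name))
            group_map[name] = group
            rule_map[name] = "representative"
        for var, name in plan.get("latent", []):
            cid = sol.cluster_of(var)
            if cid in rules:
                warnings.warn(
                    f"{group}: seeds collide in cluster {cid}; indicator {name!r} "
                    f"falls back to the seed variable {var!r} itself"
                )
                cols[name] = std.values[var]
            else:
                rules[cid] = ("latent", name)
            group_map[name] = group
            rule_map[name] = "latent"
        summary = summarize(sol, rules)
        for name in summary.columns:
            cols[name] = summary[name]

    # canonical column order: group by group, representatives then latents
    ordered: list[str] = []
    for group in ("AP", "CP", "NQ", "OQ"):
        plan = layout[group]
        for _var, name in plan.get("representative", []):
            ordered.append(name)
        for _var, name in plan.get("latent", []):
            ordered.append(name)
        for _var, name in plan.get("passthrough", []):
            ordered.append(name)
    table = pd.DataFrame(cols)[[n for n in ordered if n in cols]]
    # re-standardize every indicator column
    table = (table - table.mean()) / table.std(ddof=1)
    return IndicatorTable(table, group_map, rule_map), solutions
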