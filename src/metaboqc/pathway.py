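"""Mantel-test meta-analysis of pathway-analysis result tables.

Pathway enrichment tools report, per pathway, a p value (enrichment) and an
impact factor (topology-weighted importance of the hit metabolites). Two
comparisons — say, the same toxicant tested in two processing batches — can
be judged for agreement without assuming any pathway-level correspondence of
effect sizes: embed each table's pathways at coordinates
``(-log10 p, impact)``, form the Euclidean distance matrix over pathways,
and correlate the two distance matrices with a Mantel permutation test.
A significant positive correlation means the two comparisons organise the
pathway space the same way.

Upstream enrichment itself is out of scope; this module consumes exported
result tables (pathway id, raw p value, impact).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PathwayTable",
    "MantelResult",
    "pathway_distance_matrix",
    "mantel_test",
    "pairwise_meta",
    "read_pathway_table",
]

#: p values of exactly zero are floored here before taking -log10
P_VALUE_FLOOR = 1e-300


@dataclass
class PathwayTable:
    """One comparison's pathway-analysis results.

    ``table`` columns: ``pathway_id`` (unique), ``p_value`` in (0, 1]
    (zeros floored with a warning), ``impact`` >= 0.
    """

    table: pd.DataFrame
    comparison: str = ""

    def __post_init__(self) -> None:
        required = {"pathway_id", "p_value", "impact"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pathway table lacks columns: {sorted(missing)}")
        tbl = self.table.copy()
        tbl["pathway_id"] = tbl["pathway_id"].astype(str)
        if tbl["pathway_id"].duplicated().any():
            dup = tbl.loc[tbl["pathway_id"].duplicated(), "pathway_id"].tolist()
            raise ValueError(f"duplicate pathway ids: {dup}")
        if (tbl["p_value"] <= 0).any():
            import warnings

            warnings.warn(
                f"pathway p values <= 0 floored at {P_VALUE_FLOOR}", stacklevel=2
            )
            tbl["p_value"] = tbl["p_value"].clip(lower=P_VALUE_FLOOR)
        if (tbl["p_value"] > 1).any():
            raise ValueError("pathway p values must lie in (0, 1]")
        if (tbl["impact"] < 0).any():
            raise ValueError("pathway impact must be non-negative")
        self.table = tbl.reset_index(drop=True)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.table["pathway_id"])

    def coordinates(self) -> pd.DataFrame:
        """(-log10 p, impact) coordinates indexed by pathway id."""
        return pd.DataFrame(
            {
                "neg_log10_p": -np.log10(self.table["p_value"].to_numpy()),
                "impact": self.table["impact"].to_numpy(),
            },
            index=pd.Index(self.table["pathway_id"], name="pathway_id"),
        )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MantelResult:
    """Mantel correlation between two comparisons' pathway-distance matrices."""

    pair: tuple[str, str]
    pearson_r: float
    p_value: float
    n_permutations: int
    n_pathways_used: int
    n_dropped: int = 0
    error: str | None = field(default=None)

    @property
    def failed(self) -> bool:
        return self.error is not None


def pathway_distance_matrix(
    tbl: PathwayTable, standardize: bool = False
) -> pd.DataFrame:
    """Euclidean distance matrix of pathways in (-log10 p, impact) space.

    Coordinates are used unstandardised by default; ``standardize`` z-scores
    each axis first, for users whose impact scale dwarfs the p-value axis.
    """
    if len(tbl) < 3:
        raise ValueError("need at least 3 pathways for a distance matrix")
    coords = tbl.coordinates()
    x = coords.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


def _mantel_r(d1: np.ndarray, d2: np.ndarray) -> float:
    iu = np.triu_indices(d1.shape[0], k=1)
    a, b = d1[iu], d2[iu]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("degenerate distance matrix: zero variance in distances")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def mantel_test(
    a: PathwayTable,
    b: PathwayTable,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = False,
    exhaustive_max: int = 5,
) -> MantelResult:
    """Mantel test between two pathway tables sharing pathway ids.

    Tables are inner-joined on pathway id (non-shared pathways dropped and
    counted). ``pearson_r`` is the Pearson correlation of the upper
    triangles of the two Euclidean distance matrices; the one-sided p value
    counts joint row/column permutations of one matrix with
    ``r_perm >= r_obs``, as ``(count + 1) / (n_perm + 1)``. With
    ``exhaustive_max`` or fewer shared pathways, all permutations are
    enumerated instead and the p value is the exact fraction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    shared = [pid for pid in a.pathway_ids if pid in set(b.pathway_ids)]
    n_dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if len(shared) < 3:
        raise ValueError(f"tables share only {len(shared)} pathways; need >= 3")

    da = pathway_distance_matrix(
        PathwayTable(a.table[a.table["pathway_id"].isin(shared)], a.comparison),
        standardize=standardize,
    ).loc[shared, shared].to_numpy()
    db = pathway_distance_matrix(
        PathwayTable(b.table[b.table["pathway_id"].isin(shared)], b.comparison),
        standardize=standardize,
    ).loc[shared, shared].to_numpy()

    r_obs = _mantel_r(da, db)
    n = len(shared)
    if n <= exhaustive_max:
        perms = list(itertools.permutations(range(n)))
        count = sum(_mantel_r(da, db[np.ix_(p, p)]) >= r_obs - 1e-12 for p in perms)
        p_value = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            if _mantel_r(da, db[np.ix_(p, p)]) >= r_obs - 1e-12:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(
        pair=(a.comparison, b.comparison),
        pearson_r=r_obs,
        p_value=float(p_value),
        n_permutations=n_used,
        n_pathways_used=n,
        n_dropped=n_dropped,
    )


def pairwise_meta(
    tables: Sequence[PathwayTable],
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[list[MantelResult], dict[str, int]]:
    """Mantel tests for every unordered pair of pathway tables.

    Returns the per-pair results plus a tally of pairs significant at 0.05
    and 0.01. A degenerate pair (e.g. one table with all-identical
    coordinates) is reported as failed, not fatal.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 pathway tables")
    results: list[MantelResult] = []
    for i, j in itertools.combinations(range(len(tables)), 2):
        a, b = tables[i], tables[j]
        try:
            results.append(mantel_test(a, b, n_perm=n_perm, seed=seed + i * 1009 + j, standardize=standardize))
        except ValueError as exc:
            results.append(
                MantelResult(
                    pair=(a.comparison or str(i), b.comparison or str(j)),
                    pearson_r=float("nan"),
                    p_value=float("nan"),
                    n_permutations=0,
                    n_pathways_used=0,
                    error=str(exc),
                )
            )
    ok = [r for r in results if not r.failed]
    summary = {
        "n_pairs": len(results),
        "n_failed": len(results) - len(ok),
        "n_significant_0.05": sum(r.p_value < 0.05 for r in ok),
        "n_significant_0.01": sum(r.p_value < 0.01 for r in ok),
    }
    return results, summary


def read_pathway_table(
    path: str | Path,
    comparison: str = "",
    column_map: Mapping[str, str] | None = None,
) -> PathwayTable:
    """Read a pathway-analysis export (CSV) into a :class:`PathwayTable`.

    ``column_map`` adapts external headers, e.g. MetaboAnalyst's
    ``{"X": "pathway_id", "Raw p": "p_value", "Impact": "impact"}``.
    """
    tbl = pd.read_csv(path)
    if column_map:
        tbl = tbl.rename(columns=dict(column_map))
    return PathwayTable(tbl, comparison=comparison or Path(path).stem)


def results_to_frame(results: Sequence[MantelResult]) -> pd.DataFrame:
    """Long-format frame of Mantel results with significance stars."""

    def stars(p: float) -> str:
        if np.isnan(p):
            return ""
        return "**" if p < 0.01 else "*" if p < 0.05 else ""

    return pd.DataFrame(
        {
            "comparison": [f"{r.pair[0]}vs{r.pair[1]}" for r in results],
            "pearson_r": [r.pearson_r for r in results],
            "p_value": [r.p_value for r in results],
            "n_pathways": [r.n_pathways_used for r in results],
            "significance": [stars(r.p_value) for r in results],
            "error": [r.error or "" for r in results],
        }
    )
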