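"""Per-site differential editing between sample groups.

Reads are pooled across the samples of each group at every high-confidence
site, giving a 2x2 table of (edited, unedited) x (group1, group2) that is
tested with Fisher's exact test (two-sided).  P values are adjusted within
each comparison by the Benjamini-Hochberg step-up procedure and sites with
adjusted p < alpha are called significant.  Direction is the sign of the
pooled-ratio difference (positive when group1 is more edited).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sites import SITE_KEY


def fisher_site(
    group1: tuple[int, int], group2: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for one site.

    ``group1``/``group2`` are pooled (edited, unedited) counts.  The
    two-sided p sums all hypergeometric tables, at the observed margins,
    whose probability does not exceed the observed table's.  A table with
    an empty margin carries no information: p = 1 with a warning.
    """
    table = np.array([group1, group2], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Comparison:
    name: str
    group1: str
    group2: str


def differential_test(
    filtered: pd.DataFrame,
    sample_groups: dict[str, str],
    comparison: Comparison,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher + BH over all filtered sites for one group comparison.

    ``filtered`` is the high-confidence cohort table (per-sample rows).
    Returns one row per site with pooled counts, ratios, p, FDR-adjusted p,
    direction (+1 when group1 more edited, -1 when group2, 0 when equal)
    and the significance flag at ``alpha``.  Per-sample mean ratios are
    carried along descriptively.
    """
    df = filtered.copy()
    df["group"] = df["sample_id"].map(sample_groups)
    df = df[df["group"].isin([comparison.group1, comparison.group2])]

    pooled = (
        df.groupby(SITE_KEY + ["group"])[["edited", "unedited"]]
        .sum()
        .unstack("group", fill_value=0)
    )
    for g in (comparison.group1, comparison.group2):
        for col in ("edited", "unedited"):
            if (col, g) not in pooled.columns:
                pooled[(col, g)] = 0

    mean_ratio = (
        df.groupby(SITE_KEY + ["group"])["edit_ratio"].mean().unstack("group")
    )
    hyper = df.groupby(SITE_KEY)["hyper"].any()

    rows = []
    g1, g2 = comparison.group1, comparison.group2
    for key, row in pooled.iterrows():
        e1, u1 = int(row[("edited", g1)]), int(row[("unedited", g1)])
        e2, u2 = int(row[("edited", g2)]), int(row[("unedited", g2)])
        r1 = e1 / (e1 + u1) if e1 + u1 else np.nan
        r2 = e2 / (e2 + u2) if e2 + u2 else np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_site((e1, u1), (e2, u2))
        delta = (r1 if np.isfinite(r1) else 0.0) - (r2 if np.isfinite(r2) else 0.0)
        rows.append(
            {
                "contig": key[0],
                "pos": key[1],
                "strand": key[2],
                "edited_1": e1,
                "unedited_1": u1,
                "edited_2": e2,
                "unedited_2": u2,
                "ratio_1": r1,
                "ratio_2": r2,
                "mean_sample_ratio_1": mean_ratio.loc[key].get(g1, np.nan),
                "mean_sample_ratio_2": mean_ratio.loc[key].get(g2, np.nan),
                "delta_ratio": delta,
                "direction": int(np.sign(delta)),
                "p": p,
                "hyper": bool(hyper.loc[key]),
            }
        )
    res = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "strand", "edited_1", "unedited_1", "edited_2",
            "unedited_2", "ratio_1", "ratio_2", "mean_sample_ratio_1",
            "mean_sample_ratio_2", "delta_ratio", "direction", "p", "hyper",
        ],
    )
    if len(res):
        res["p_adj"] = adjust_fdr(res["p"].to_numpy())
        res["significant"] = res["p_adj"] < alpha
    else:
        res["p_adj"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    res.attrs["comparison"] = comparison.name
    res.attrs["groups"] = (g1, g2)
    res.attrs["alpha"] = alpha
    return res.sort_values(SITE_KEY, kind="stable").reset_index(drop=True)


def summarize_directions(
    results: dict[str, pd.DataFrame] | pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Counts of significant sites per direction per comparison (the
    stacked-bar summary).  Direction-0 sites are excluded."""
    if isinstance(results, pd.DataFrame):
        results = {results.attrs.get("comparison", "comparison"): results}
    rows = []
    for name, res in results.items():
        sig = res[(res["p_adj"] < alpha) & (res["direction"] != 0)]
        rows.append(
            {
                "comparison": name,
                "up_in_group1": int((sig["direction"] > 0).sum()),
                "up_in_group2": int((sig["direction"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["comparison", "up_in_group1", "up_in_group2"])


def top_sites(
    results: pd.DataFrame, k: int = 500, repeat_classes: pd.Series | None = None
) -> pd.DataFrame:
    """Top-k differentially edited sites.

    Ranked by adjusted p ascending, then |delta ratio| descending, then
    coordinate; asking for more sites than exist returns them all.
    ``repeat_classes`` (indexed like ``results``) attaches repeat-class
    labels when supplied.
    """
    res = results.copy()
    if repeat_classes is not None:
        res["repeat_class"] = repeat_classes
    res["_absd"] = res["delta_ratio"].abs()
    res = res.sort_values(
        ["p_adj", "_absd", "contig", "pos", "strand"],
        ascending=[True, False, True, True, True],
        kind="stable",
    ).drop(columns="_absd")
    return res.head(max(k, 0)).reset_index(drop=True)
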