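"""Threshold-sweep classification, group comparisons, and reporting.

Each subject carries a metacommunity-level neutrality pseudo P-value
(``P_M``), a local-level one (``P_L``), the hybrid-model chi-square
P-value and the per-niche hybrid P-values.  At each threshold ``P_t`` a
model "passes" iff its P-value exceeds ``P_t``, yielding a four-way
classification (MSN-only / NNH-only / both / neither).  Group effects are
assessed with two-sided Fisher exact tests on metacommunity pass/fail
counts and two-sample t-tests on local passing percentages.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import write_manifest

logger = logging.getLogger(__name__)

__all__ = ["CATEGORIES", "DEFAULT_THRESHOLDS", "ClassificationTable",
           "classify", "four_way_percentages", "sweep_tables",
           "group_compare", "make_report"]

CATEGORIES = ("MSN-only", "NNH-only", "both", "neither")
DEFAULT_THRESHOLDS = (0.05, 0.5, 0.9, 0.95)


def classify(P_msn: float, P_nnh: float, P_t: float) -> str:
    """Four-way category of a subject from its two metacommunity P-values."""
    if not 0.0 < P_t < 1.0:
        raise ValueError(f"P_t={P_t} must lie in (0, 1)")
    for name, p in (("P_msn", P_msn), ("P_nnh", P_nnh)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    msn, nnh = P_msn > P_t, P_nnh > P_t
    if msn and nnh:
        return "both"
    if msn:
        return "MSN-only"
    if nnh:
        return "NNH-only"
    return "neither"


def four_way_percentages(counts: Sequence[int], n: int) -> list[float]:
    """Category counts -> percentages of n, rounded to 1 decimal."""
    if sum(counts) != n:
        raise ValueError("category counts must sum to n")
    return [round(100.0 * c / n, 1) for c in counts]


@dataclasses.dataclass
class ClassificationTable:
    """Per-subject test results feeding the sweep and group comparisons.

    ``subjects`` columns: subject_id, group, P_M, P_L (multi-site neutral
    meta/local), P_nnh (hybrid metacommunity chi-square P).
    ``nnh_local_p`` maps subject_id to that subject's per-niche P-values.
    """

    subjects: pd.DataFrame
    nnh_local_p: dict[str, np.ndarray] = dataclasses.field(
        default_factory=dict)

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "P_M", "P_L", "P_nnh"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")

    def nnh_local_pct(self, subject_id: str, P_t: float) -> float:
        ps = np.asarray(self.nnh_local_p.get(subject_id, ()))
        ps = ps[~np.isnan(ps)]
        if ps.size == 0:
            return float("nan")
        return 100.0 * float((ps > P_t).sum()) / ps.size

    def category(self, subject_id: str, P_t: float) -> str:
        row = self.subjects.set_index("subject_id").loc[subject_id]
        return classify(float(row["P_M"]), float(row["P_nnh"]), P_t)


def sweep_tables(results: ClassificationTable,
                 thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Passing-rate and four-way-category tables per group and overall.

    Returns ``(passing, categories)``.  ``passing`` rows: one per
    (group|Overall, threshold) with the percent of subjects passing each
    model at the metacommunity level, the percent passing the neutral
    local test, and the mean percent of niches passing the hybrid local
    test.  ``categories`` rows: one per (group|Overall, threshold,
    category) with counts and percentages (1 decimal).
    """
    df = results.subjects
    groups = [(g, sub) for g, sub in df.groupby("group", sort=False)]
    empty = [g for g, sub in groups if len(sub) == 0]
    for g in empty:  # pragma: no cover - groupby drops empties already
        logger.warning("empty group %s omitted", g)
    blocks = groups + [("Overall", df)]
    passing_rows, cat_rows = [], []
    for label, sub in blocks:
        n = len(sub)
        if n == 0:
            continue
        for P_t in thresholds:
            msn_meta = 100.0 * float((sub["P_M"] > P_t).mean())
            msn_local = 100.0 * float((sub["P_L"] > P_t).mean())
            nnh_meta = 100.0 * float((sub["P_nnh"] > P_t).mean())
            local_pcts = [results.nnh_local_pct(s, P_t)
                          for s in sub["subject_id"]]
            local_pcts = [p for p in local_pcts if not np.isnan(p)]
            nnh_local = float(np.mean(local_pcts)) if local_pcts \
                else float("nan")
            passing_rows.append({
                "group": label, "n": n, "P_t": P_t,
                "MSN_meta_pct": round(msn_meta, 1),
                "MSN_local_pct": round(msn_local, 1),
                "NNH_meta_pct": round(nnh_meta, 1),
                "NNH_local_pct": round(nnh_local, 1),
            })
            cats = [classify(pm, pn, P_t)
                    for pm, pn in zip(sub["P_M"], sub["P_nnh"])]
            counts = [cats.count(c) for c in CATEGORIES]
            pcts = four_way_percentages(counts, n)
            for c, cnt, pct in zip(CATEGORIES, counts, pcts):
                cat_rows.append({"group": label, "n": n, "P_t": P_t,
                                 "category": c, "N": cnt, "pct": pct})
    return pd.DataFrame(passing_rows), pd.DataFrame(cat_rows)


def _resolve_groups(df: pd.DataFrame,
                    merge: Mapping[str, Sequence[str]] | None,
                    ) -> dict[str, pd.DataFrame]:
    out = {g: sub for g, sub in df.groupby("group", sort=False)}
    for label, members in (merge or {}).items():
        parts = [out[m] for m in members if m in out]
        if parts:
            out[label] = pd.concat(parts)
    return out


def group_compare(results: ClassificationTable,
                  pairs: Sequence[tuple[str, str]] | None = None,
                  thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                  merge: Mapping[str, Sequence[str]] | None = None,
                  welch: bool = False) -> pd.DataFrame:
    """Fisher-exact and t-test comparisons of passing rates between groups.

    For each group pair and threshold: a two-sided Fisher exact test on
    the 2x2 metacommunity pass/fail table (per model), and a two-sided
    two-sample t-test (pooled variance by default, Welch optional) on the
    per-subject local passing percentages.  ``merge`` defines composite
    groups, e.g. ``{"BV": ["ABV", "SBV"], "HEA": ["HEA-1", "HEA-2"]}``.
    """
    df = results.subjects
    groups = _resolve_groups(df, merge)
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for ga, gb in pairs:
        if ga not in groups or gb not in groups:
            raise ValueError(f"unknown group in pair ({ga}, {gb})")
        a, b = groups[ga], groups[gb]
        for P_t in thresholds:
            for model, meta_col in (("MSN", "P_M"), ("NNH", "P_nnh")):
                pa, pb = (a[meta_col] > P_t).sum(), (b[meta_col] > P_t).sum()
                table = [[int(pa), int(len(a) - pa)],
                         [int(pb), int(len(b) - pb)]]
                fisher_p = float(stats.fisher_exact(
                    table, alternative="two-sided")[1])
                rows.append({"pair": f"{ga} vs {gb}", "P_t": P_t,
                             "model": model, "level": "metacommunity",
                             "test": "fisher", "P": fisher_p, "note": ""})
                if model == "MSN":
                    la = 100.0 * (a["P_L"] > P_t).to_numpy(dtype=float)
                    lb = 100.0 * (b["P_L"] > P_t).to_numpy(dtype=float)
                else:
                    la = np.array([results.nnh_local_pct(s, P_t)
                                   for s in a["subject_id"]])
                    lb = np.array([results.nnh_local_pct(s, P_t)
                                   for s in b["subject_id"]])
                la, lb = la[~np.isnan(la)], lb[~np.isnan(lb)]
                if la.size < 2 or lb.size < 2:
                    rows.append({"pair": f"{ga} vs {gb}", "P_t": P_t,
                                 "model": model, "level": "local",
                                 "test": "t", "P": float("nan"),
                                 "note": "group too small"})
                    continue
                if np.var(la) == 0.0 and np.var(lb) == 0.0:
                    # degenerate zero-variance samples: identical rates are
                    # indistinguishable (P=1), unequal ones trivially differ
                    t_p = 1.0 if la.mean() == lb.mean() else 0.0
                else:
                    t_p = float(stats.ttest_ind(la, lb,
                                                equal_var=not welch).pvalue)
                rows.append({"pair": f"{ga} vs {gb}", "P_t": P_t,
                             "model": model, "level": "local", "test": "t",
                             "P": t_p, "note": ""})
    return pd.DataFrame(rows)


def make_report(outdir: str | Path, msn_rows, nnh_rows,
                results: ClassificationTable,
                thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                comparisons: pd.DataFrame | None = None,
                sad_plots: Mapping[str, object] | None = None,
                manifest: Mapping | None = None) -> dict[str, Path]:
    """Write every report artifact: result tables, sweep tables, figures.

    ``sad_plots`` maps subject_id to a fitted
    :class:`~nicheneutral.nnh.NicheNeutralHybridModel` (or its result)
    whose binned observed-vs-expected SAD is plotted.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .data_model import write_result_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["msn_results"] = outdir / "msn_results.tsv"
    write_result_tables(list(msn_rows), paths["msn_results"], schema="msn")
    paths["nnh_results"] = outdir / "nnh_results.tsv"
    write_result_tables(list(nnh_rows), paths["nnh_results"], schema="nnh")

    passing, categories = sweep_tables(results, thresholds)
    paths["passing"] = outdir / "passing_rates.tsv"
    passing.to_csv(paths["passing"], sep="\t", index=False)
    paths["categories"] = outdir / "categories.tsv"
    categories.to_csv(paths["categories"], sep="\t", index=False)

    if comparisons is None:
        try:
            comparisons = group_compare(results, thresholds=thresholds)
        except ValueError:
            comparisons = pd.DataFrame()
    paths["comparisons"] = outdir / "group_comparisons.tsv"
    comparisons.to_csv(paths["comparisons"], sep="\t", index=False)

    paths["subjects"] = outdir / "subject_pvalues.tsv"
    results.subjects.to_csv(paths["subjects"], sep="\t", index=False)

    # bar chart of passing percentages per group per threshold
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, col, title in zip(axes, ("MSN_meta_pct", "NNH_meta_pct"),
                              ("Multi-site neutral", "Niche-neutral hybrid")):
        pivot = passing.pivot(index="group", columns="P_t", values=col)
        pivot.plot.bar(ax=ax, legend=False)
        ax.set_title(f"{title} (metacommunity)")
        ax.set_ylabel("% subjects passing")
    axes[1].legend(title="P_t", fontsize=8)
    fig.tight_layout()
    paths["passing_fig"] = outdir / "passing_rates.png"
    fig.savefig(paths["passing_fig"], dpi=120)
    plt.close(fig)

    for sid, model in (sad_plots or {}).items():
        binned = getattr(model, "result_", model)
        binned = getattr(binned, "binned", None)
        if binned is None:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        idx = np.arange(len(binned.O))
        ax.bar(idx - 0.2, binned.O, width=0.4, label="observed")
        ax.bar(idx + 0.2, binned.E, width=0.4, label="expected")
        labels = [f"{lo}-{hi - 1}" for lo, hi in zip(binned.bin_edges[:-1],
                                                     binned.bin_edges[1:])]
        ax.set_xticks(idx, labels, rotation=45, fontsize=7)
        ax.set_xlabel("abundance class")
        ax.set_ylabel("number of species")
        ax.set_title(f"{sid}: observed vs predicted SAD")
        ax.legend()
        fig.tight_layout()
        p = outdir / f"sad_{sid}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"sad_{sid}"] = p

    write_manifest(outdir / "run_manifest.json", **(dict(manifest or {})))
    paths["manifest"] = outdir / "run_manifest.json"
    return paths
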