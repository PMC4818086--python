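"""Group statistics and reporting for consolidated morphometric tables.

The analysis stage consolidates per-structure tables across conditions and
replicates into a single :class:`~pandas.DataFrame` (the study table), then

* summarizes every parameter per condition x replicate (mean, SD,
  coefficient of variation, median);
* compares conditions with one-way ANOVA, and — when exactly two conditions
  are present — a two-sided Wilcoxon rank-sum test (exact enumeration for
  group sizes up to 10, normal approximation with tie correction beyond);
  the reported p-value is the LARGER of the two, a deliberately conservative
  convention;
* runs a correlation-matrix PCA over standardized parameters to expose which
  variables drive the variance between groups;
* estimates per-replicate density curves (shared Silverman bandwidth) whose
  superimposition diagnoses within-treatment reproducibility, quantified by
  pairwise Kolmogorov-Smirnov distances.

The experimental unit for hypothesis tests defaults to the per-stack mean
(each stack is one replicate of the experiment); pooling individual
structures is available but constitutes pseudo-replication.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PCAResult",
    "ReproducibilityResult",
    "consolidate",
    "summarize",
    "exact_rank_sum_p",
    "wilcoxon_rank_sum",
    "compare_groups",
    "run_pca",
    "reproducibility_curves",
    "generate_report",
]

log = logging.getLogger(__name__)

#: parameters reported by default (must exist in the study table)
DEFAULT_PARAMETERS = [
    "volume", "elon1", "elon2", "sphericity", "rve", "q",
    "n_lumena", "rlv", "n_branches", "total_length", "has_multiple_branches",
]

LUMEN_COLUMNS = ["n_lumena", "lumen_volume", "rlv", "rlv_inverse", "q"]
BRANCHING_COLUMNS = ["n_branches", "total_length", "has_multiple_branches"]


def consolidate(
    structure_tables: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    include_lumen: bool = True,
    include_branching: bool = True,
) -> pd.DataFrame:
    """Join per-stack structure tables with condition/replicate metadata.

    ``metadata`` must map every stack id to a condition and replicate
    (columns ``stack, condition, replicate``). Lumen and branching columns
    are kept only when the corresponding analysis is included; structures
    lacking lumen data get ``n_lumena = 0, rlv = 0``. Duplicate
    (stack, label) pairs are an error, as are stacks without metadata.
    """
    meta = metadata.set_index("stack")
    missing = [s for s in structure_tables if s not in meta.index]
    if missing:
        raise ValueError(f"stacks without metadata: {missing}")
    frames = []
    for stack_id, tbl in structure_tables.items():
        t = tbl.copy()
        t.insert(0, "stack", stack_id)
        t.insert(1, "condition", meta.loc[stack_id, "condition"])
        t.insert(2, "replicate", meta.loc[stack_id, "replicate"])
        frames.append(t)
    study = pd.concat(frames, ignore_index=True)
    if study.duplicated(subset=["stack", "label"]).any():
        dups = study.loc[study.duplicated(subset=["stack", "label"]), ["stack", "label"]]
        raise ValueError(f"duplicate (stack, label) rows: {dups.values.tolist()}")
    if include_lumen:
        for col, default in (("n_lumena", 0), ("rlv", 0.0)):
            if col not in study.columns:
                study[col] = default
            else:
                study[col] = study[col].fillna(default)
    else:
        study = study.drop(columns=[c for c in LUMEN_COLUMNS if c in study.columns])
    if not include_branching:
        study = study.drop(columns=[c for c in BRANCHING_COLUMNS if c in study.columns])
    return study


def summarize(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per (condition, replicate) mean, SD, CV and median of one parameter.

    Sample SD (ddof=1); CV = SD/mean, missing when the mean is zero; NaNs in
    the parameter are excluded with a logged count.
    """
    if parameter not in table.columns:
        raise KeyError(f"parameter {parameter!r} not in table")
    rows = []
    for (cond, rep), grp in table.groupby(["condition", "replicate"], sort=True):
        vals = pd.to_numeric(grp[parameter], errors="coerce")
        n_nan = int(vals.isna().sum())
        if n_nan:
            log.info("summarize(%s): excluded %d missing values in %s/%s",
                     parameter, n_nan, cond, rep)
        vals = vals.dropna().to_numpy(dtype=float)
        row = {"condition": cond, "replicate": rep, "parameter": parameter,
               "n": len(vals)}
        if len(vals):
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            if mean != 0:
                cv = sd / mean
            else:
                cv = np.nan
                log.warning("summarize(%s): zero mean in %s/%s, CV undefined",
                            parameter, cond, rep)
            row.update(mean=mean, sd=sd, cv=cv, median=float(np.median(vals)))
        else:
            row.update(mean=np.nan, sd=np.nan, cv=np.nan, median=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _rank_sum_distribution(int_ranks: np.ndarray, n: int) -> np.ndarray:
    """Counts of subsets of size n by rank sum (dynamic programming).

    ``int_ranks`` are integers (midranks doubled); entry s of the returned
    vector is the number of n-subsets of the pooled ranks summing to s.
    """
    total = int(int_ranks.sum())
    dp = np.zeros((n + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in int_ranks:
        r = int(r)
        for k in range(min(n, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n]


def exact_rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value by full enumeration.

    The permutation distribution of the rank sum of the first sample (ties
    handled with midranks) is enumerated over all C(n+m, n) group labelings;
    p = P(|W - E[W]| >= |w_obs - E[W]|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    ir = np.round(2 * ranks).astype(np.int64)  # midranks doubled -> integers
    w_obs = ir[:n].sum()
    counts = _rank_sum_distribution(ir, n)
    total = counts.sum()
    mu = n * ir.sum() / (n + m)
    dev = abs(w_obs - mu)
    sums = np.arange(len(counts))
    p = counts[np.abs(sums - mu) >= dev - 1e-9].sum() / total
    return float(min(1.0, p))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], exact_max_n: int = 10) -> float:
    """Two-sided rank-sum p: exact enumeration for small groups, otherwise a
    tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if max(len(x), len(y)) <= exact_max_n:
        return exact_rank_sum_p(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass
class TestResult:
    """Outcome of one parameter's group comparison."""

    parameter: str
    groups: list[str]
    unit: str
    n_per_group: list[int]
    anova_p: float
    wilcoxon_p: float | None
    reported_p: float
    group_means: list[float]

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "groups": "|".join(map(str, self.groups)),
            "unit": self.unit,
            "n_per_group": "|".join(map(str, self.n_per_group)),
            "anova_p": self.anova_p,
            "wilcoxon_p": self.wilcoxon_p if self.wilcoxon_p is not None else np.nan,
            "reported_p": self.reported_p,
            "group_means": "|".join(f"{m:.6g}" for m in self.group_means),
        }


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    unit: str = "stack",
) -> TestResult:
    """Compare conditions on one parameter; report the larger p-value.

    ``unit="stack"`` (default) aggregates the parameter to per-stack means —
    the stack is the experimental replicate; ``unit="structure"`` pools
    individual structures (pseudo-replication, use knowingly). One-way ANOVA
    is always run; the Wilcoxon rank-sum test is added when exactly two
    conditions are present, and the reported p is the maximum of the two.
    """
    if unit not in ("stack", "structure"):
        raise ValueError("unit must be 'stack' or 'structure'")
    work = table[["condition", "stack", parameter]].copy()
    work[parameter] = pd.to_numeric(work[parameter], errors="coerce")
    work = work.dropna(subset=[parameter])
    if unit == "stack":
        work = work.groupby(["condition", "stack"], as_index=False)[parameter].mean()
    groups: list[str] = []
    samples: list[np.ndarray] = []
    for cond, grp in work.groupby("condition", sort=True):
        vals = grp[parameter].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(
                f"group {cond!r} has {len(vals)} {unit} unit(s); need >= 2 for testing"
            )
        groups.append(str(cond))
        samples.append(vals)
    if len(samples) < 2:
        raise ValueError("need at least two conditions to compare")
    if all(np.allclose(s, samples[0][0]) for s in samples):
        anova_p = 1.0  # identical constant groups: no evidence of difference
    else:
        anova_p = float(sps.f_oneway(*samples).pvalue)
        if np.isnan(anova_p):
            anova_p = 1.0
    wilcoxon_p = wilcoxon_rank_sum(samples[0], samples[1]) if len(samples) == 2 else None
    reported = max(p for p in (anova_p, wilcoxon_p) if p is not None)
    return TestResult(
        parameter=parameter,
        groups=groups,
        unit=unit,
        n_per_group=[len(s) for s in samples],
        anova_p=anova_p,
        wilcoxon_p=wilcoxon_p,
        reported_p=reported,
        group_means=[float(s.mean()) for s in samples],
    )


@dataclass
class PCAResult:
    """Correlation-matrix PCA of standardized morphometric variables."""

    variables: list[str]
    loadings: np.ndarray  # (n_variables, n_components), orthonormal columns
    scores: np.ndarray  # (n_rows, n_components)
    explained_variance_ratio: np.ndarray
    row_index: np.ndarray  # indices of the table rows used (NaN rows dropped)


def run_pca(table: pd.DataFrame, variables: Sequence[str]) -> PCAResult:
    """PCA on standardized variables (correlation-matrix convention).

    Zero-variance variables are dropped with a warning (they carry no trend
    information); rows with missing values are excluded with a logged count.
    """
    from sklearn.decomposition import PCA

    data = table[list(variables)].apply(pd.to_numeric, errors="coerce")
    keep_rows = ~data.isna().any(axis=1)
    n_dropped = int((~keep_rows).sum())
    if n_dropped:
        log.info("run_pca: dropped %d row(s) with missing values", n_dropped)
    data = data.loc[keep_rows]
    sd = data.std(ddof=1)
    degenerate = [v for v in variables if not np.isfinite(sd[v]) or sd[v] == 0]
    if degenerate:
        log.warning("run_pca: dropping zero-variance variable(s) %s", degenerate)
    used = [v for v in variables if v not in degenerate]
    if len(used) < 2:
        raise ValueError("need at least two variables with nonzero variance")
    Z = (data[used] - data[used].mean()) / data[used].std(ddof=1)
    pca = PCA(n_components=len(used), svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    return PCAResult(
        variables=used,
        loadings=pca.components_.T,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        row_index=data.index.to_numpy(),
    )


@dataclass
class ReproducibilityResult:
    """Per-replicate density curves and their pairwise KS distances."""

    parameter: str
    condition: str
    grid: np.ndarray
    densities: dict[str, np.ndarray]  # replicate -> density on grid
    ks_distance: pd.DataFrame | None  # pairwise, None with a single replicate


def reproducibility_curves(
    table: pd.DataFrame, parameter: str, condition: str
) -> ReproducibilityResult:
    """Kernel density estimate of one parameter per replicate of a condition.

    A single bandwidth (Silverman's rule on the pooled sample) is shared by
    all replicates so curve shapes are directly comparable; superimposed
    curves indicate reproducible replicates. The pairwise two-sample
    Kolmogorov-Smirnov statistic quantifies the overlap (0 = identical).
    """
    sel = table[table["condition"] == condition]
    if sel.empty:
        raise ValueError(f"condition {condition!r} not in table")
    pooled = pd.to_numeric(sel[parameter], errors="coerce").dropna().to_numpy(dtype=float)
    if pooled.std(ddof=1) == 0:
        pooled = pooled + np.array([0.0])  # degenerate; kde below falls back
    # Silverman's rule-of-thumb bandwidth on the pooled sample
    n = len(pooled)
    sigma = pooled.std(ddof=1)
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    spread = min(sigma, iqr / 1.349) if iqr > 0 else sigma
    h = 0.9 * spread * n ** (-1 / 5) if spread > 0 else 1.0

    grid = np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, 512)
    densities: dict[str, np.ndarray] = {}
    samples: dict[str, np.ndarray] = {}
    for rep, grp in sel.groupby("replicate", sort=True):
        vals = pd.to_numeric(grp[parameter], errors="coerce").dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        samples[str(rep)] = vals
        # fixed absolute bandwidth h: sum of normal kernels
        diff = (grid[:, None] - vals[None, :]) / h
        dens = np.exp(-0.5 * diff**2).sum(axis=1) / (len(vals) * h * np.sqrt(2 * np.pi))
        densities[str(rep)] = dens

    ks = None
    reps = sorted(samples)
    if len(reps) >= 2:
        mat = pd.DataFrame(0.0, index=reps, columns=reps)
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                d = float(sps.ks_2samp(samples[a], samples[b]).statistic)
                mat.loc[a, b] = mat.loc[b, a] = d
        ks = mat
    else:
        log.warning("reproducibility_curves: single replicate, no KS diagnostic")
    return ReproducibilityResult(parameter, condition, grid, densities, ks)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def generate_report(
    study: pd.DataFrame,
    out_dir: str | Path,
    parameters: Sequence[str] | None = None,
    unit: str = "stack",
    bh_correction: bool = False,
) -> dict:
    """Write the full analysis report: per-parameter summary CSV, test CSV,
    distribution + boxplot figures, a PCA factor map, and an index file.

    Deterministic: the same study table produces byte-identical CSVs.
    Returns the index (paths + test results) as a dict.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_test").write_text("")
        (out / ".write_test").unlink()
    except OSError as exc:
        raise RuntimeError(f"output directory {out} is not writable: {exc}") from exc

    if parameters is None:
        parameters = [p for p in DEFAULT_PARAMETERS if p in study.columns]
    conditions = sorted(study["condition"].unique())

    index: dict = {"parameters": list(parameters), "conditions": conditions, "files": []}
    summaries, tests = [], []
    for param in parameters:
        summaries.append(summarize(study, param))
        try:
            tests.append(compare_groups(study, param, unit=unit).as_row())
        except ValueError as exc:
            log.warning("report: skipping test for %s (%s)", param, exc)

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for cond in conditions:
            vals = pd.to_numeric(
                study.loc[study["condition"] == cond, param], errors="coerce"
            ).dropna().astype(float)
            if len(vals) > 1 and vals.std() > 0:
                kde = sps.gaussian_kde(vals, bw_method="silverman")
                xs = np.linspace(vals.min(), vals.max(), 256)
                axes[0].plot(xs, kde(xs), label=str(cond))
        axes[0].set_title(f"{param}: distribution")
        if axes[0].lines:
            axes[0].legend()
        data = [
            pd.to_numeric(study.loc[study["condition"] == c, param], errors="coerce")
            .dropna().astype(float)
            for c in conditions
        ]
        axes[1].boxplot(data, tick_labels=[str(c) for c in conditions])
        axes[1].set_title(f"{param}: by condition")
        fig.tight_layout()
        figpath = out / f"{param}.png"
        fig.savefig(figpath, dpi=100)
        plt.close(fig)
        index["files"].append(figpath.name)

    pd.concat(summaries, ignore_index=True).to_csv(out / "summary.csv", index=False)
    tests_df = pd.DataFrame(tests)
    if bh_correction and not tests_df.empty:
        tests_df["bh_q"] = benjamini_hochberg(tests_df["reported_p"].to_numpy())
    tests_df.to_csv(out / "tests.csv", index=False)
    index["files"] += ["summary.csv", "tests.csv"]

    numeric = [p for p in parameters if study[p].dtype != object]
    try:
        pca = run_pca(study, numeric)
        fig, axes = plt.subplots(1, 2, figsize=(11, 5))
        for i, v in enumerate(pca.variables):
            axes[0].annotate(
                v, xy=(0, 0), xytext=(pca.loadings[i, 0], pca.loadings[i, 1]),
                arrowprops=dict(arrowstyle="<-"),
            )
        axes[0].set_xlim(-1.1, 1.1); axes[0].set_ylim(-1.1, 1.1)
        axes[0].axhline(0, lw=0.5); axes[0].axvline(0, lw=0.5)
        axes[0].set_xlabel(f"PC1 ({pca.explained_variance_ratio[0]:.0%})")
        axes[0].set_ylabel(f"PC2 ({pca.explained_variance_ratio[1]:.0%})")
        axes[0].set_title("variable factor map")
        conds = study.loc[pca.row_index, "condition"]
        for cond in conditions:
            sel = (conds == cond).to_numpy()
            axes[1].scatter(pca.scores[sel, 0], pca.scores[sel, 1], s=8, label=str(cond))
        axes[1].legend(); axes[1].set_title("individuals")
        fig.tight_layout()
        fig.savefig(out / "pca.png", dpi=100)
        plt.close(fig)
        index["files"].append("pca.png")
        index["pca_explained_variance"] = pca.explained_variance_ratio.tolist()
    except ValueError as exc:
        log.warning("report: PCA skipped (%s)", exc)

    index["tests"] = tests
    with open(out / "index.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    return index
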