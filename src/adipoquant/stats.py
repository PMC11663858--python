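"""Group statistics and tabular assay calculations.

Covers the statistical toolbox used around the imaging readouts:
Kruskal-Wallis with Dunn post hoc comparisons (Holm-adjusted) for
droplet-count percentages, two-way ANOVA with Tukey HSD for eluted-dye
and qPCR data, the 2^-ddCt relative-expression transform, and the
Bradford standard-curve / eluate-normalization arithmetic.

Kruskal-Wallis and ANOVA delegate to scipy/statsmodels; the Dunn z
statistics (with tie correction) are computed here because no installed
package exposes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KruskalResult",
    "AnovaResult",
    "StandardCurve",
    "kruskal_wallis_multi",
    "two_way_anova",
    "ddct",
    "fit_standard_curve",
    "normalize_eluate",
]


@dataclass
class KruskalResult:
    h: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj (Holm)


@dataclass
class AnovaResult:
    table: pd.DataFrame               # effect, sum_sq, df, F, p (type II)
    posthoc: dict[str, pd.DataFrame]  # Tukey HSD per factor and for cells


@dataclass
class StandardCurve:
    slope: float
    intercept: float

    def predict_conc(self, absorbance: float | np.ndarray) -> float | np.ndarray:
        """Invert the fitted line: concentration for a measured absorbance."""
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


def _group_arrays(table: pd.DataFrame, value: str, group: str) -> dict[str, np.ndarray]:
    groups = {str(k): np.asarray(v, dtype=float)
              for k, v in table.groupby(group, sort=True)[value]}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    return groups


def kruskal_wallis_multi(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
) -> KruskalResult:
    """Kruskal-Wallis H test with Dunn pairwise comparisons.

    H uses the standard tie correction (via scipy).  Pairwise z statistics
    follow Dunn's method on the pooled ranks, with the tie term
    sum(t^3 - t) in the variance; two-sided normal p-values are adjusted by
    Holm's step-down procedure.
    """
    groups = _group_arrays(table, value, group)
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)

    if np.ptp(pooled) == 0:
        # no variation anywhere: no evidence of a group effect
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        pairwise = pd.DataFrame({
            "group_a": [a for a, _ in pairs], "group_b": [b for _, b in pairs],
            "z": 0.0, "p_raw": 1.0, "p_adj": 1.0,
        })
        return KruskalResult(h=0.0, p_value=1.0, pairwise=pairwise)

    h, p = ss.kruskal(*[groups[g] for g in names])

    ranks = ss.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) \
                * (1.0 / sizes[a] + 1.0 / sizes[b])
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p_raw": 2.0 * ss.norm.sf(abs(z))})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return KruskalResult(h=float(h), p_value=float(p), pairwise=pairwise)


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
) -> AnovaResult:
    """Two-way ANOVA (type-II sums of squares) with Tukey HSD post hoc.

    Requires both factors fully crossed with at least 2 replicates per
    design cell.  Post hoc Tukey tables are produced per factor (pooling
    over the other) and for the crossed cell combinations.  Effects with
    zero between-group sum of squares are reported with F = 0, p = 1.
    """
    df = table[[value, factor_a, factor_b]].copy()
    df.columns = ["y", "fa", "fb"]
    cell_sizes = df.groupby(["fa", "fb"], sort=True).size()
    n_a = df["fa"].nunique()
    n_b = df["fb"].nunique()
    if len(cell_sizes) < n_a * n_b:
        raise ValueError("empty design cell: every factor combination needs observations")
    if (cell_sizes < 2).any():
        bad = cell_sizes[cell_sizes < 2].index[0]
        raise ValueError(f"design cell {bad} has fewer than 2 replicates")

    model = ols("y ~ C(fa) * C(fb)", data=df).fit()
    aov = anova_lm(model, typ=2)
    aov = aov.rename(index={"C(fa)": factor_a, "C(fb)": factor_b,
                            "C(fa):C(fb)": f"{factor_a}:{factor_b}"})
    aov = aov.rename(columns={"PR(>F)": "p"})
    for idx in aov.index:
        if idx != "Residual" and abs(aov.loc[idx, "sum_sq"]) < 1e-12:
            aov.loc[idx, ["F", "p"]] = [0.0, 1.0]

    posthoc: dict[str, pd.DataFrame] = {}
    if df["y"].nunique() == 1:
        # Tukey is degenerate without any variance; report trivial tables
        for name, col in ((factor_a, "fa"), (factor_b, "fb")):
            levels = sorted(df[col].unique())
            pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
            posthoc[name] = pd.DataFrame({"group1": [a for a, _ in pairs],
                                          "group2": [b for _, b in pairs],
                                          "meandiff": 0.0, "p-adj": 1.0})
    else:
        for name, col in ((factor_a, "fa"), (factor_b, "fb")):
            res = pairwise_tukeyhsd(df["y"], df[col])
            posthoc[name] = pd.DataFrame(res.summary().data[1:],
                                         columns=res.summary().data[0])
        cells = df["fa"].astype(str) + "/" + df["fb"].astype(str)
        res = pairwise_tukeyhsd(df["y"], cells)
        posthoc["cells"] = pd.DataFrame(res.summary().data[1:],
                                        columns=res.summary().data[0])
    return AnovaResult(table=aov, posthoc=posthoc)


def ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    control_samples: list[str],
    sample: str = "sample",
    gene: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """2^-ddCt relative expression, control-group mean normalized to 1.

    For each target gene, dCt = Ct_target - Ct_reference per sample; the
    fold change 2^-dCt is divided by the control group's mean fold change,
    so the arithmetic mean of the control samples is exactly 1 for every
    gene.  Raises when a sample lacks the reference gene or a Ct is not
    positive.
    """
    df = ct[[sample, gene, ct_col]].copy()
    df.columns = ["sample", "gene", "ct"]
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ref = df[df["gene"] == reference_gene].set_index("sample")["ct"]
    targets = df[df["gene"] != reference_gene]
    if targets.empty:
        raise ValueError("no target genes besides the reference")
    missing = set(targets["sample"]) - set(ref.index)
    if missing:
        raise ValueError(f"samples missing reference gene {reference_gene!r}: {sorted(missing)}")
    controls = set(control_samples)
    if not controls <= set(targets["sample"]):
        raise ValueError("control samples absent from the table")

    rows = []
    for g, sub in targets.groupby("gene", sort=True):
        dct = sub["ct"].to_numpy() - ref.loc[sub["sample"]].to_numpy()
        fold = 2.0 ** (-dct)
        is_ctrl = sub["sample"].isin(controls).to_numpy()
        if not is_ctrl.any():
            raise ValueError(f"gene {g!r} has no control-sample observations")
        rel = fold / fold[is_ctrl].mean()
        for s, d, r, c in zip(sub["sample"], dct, rel, is_ctrl):
            rows.append({"sample": s, "gene": g, "dct": d,
                         "rel_expression": r, "is_control": bool(c)})
    return pd.DataFrame(rows)


def fit_standard_curve(standards: pd.DataFrame | list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares line through (concentration, absorbance) standards.

    Duplicate concentrations are averaged before fitting.  A degenerate
    curve (zero slope or fewer than 2 distinct concentrations) raises.
    """
    if not isinstance(standards, pd.DataFrame):
        standards = pd.DataFrame(standards, columns=["conc", "abs"])
    else:
        standards = standards.rename(columns=dict(zip(standards.columns[:2], ["conc", "abs"])))
    means = standards.groupby("conc", sort=True)["abs"].mean()
    if len(means) < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    fit = ss.linregress(means.index.to_numpy(dtype=float), means.to_numpy(dtype=float))
    if abs(fit.slope) < 1e-12:
        raise ValueError("degenerate standard curve: slope is zero")
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept))


def normalize_eluate(a500: float | np.ndarray, protein: float | np.ndarray) -> float | np.ndarray:
    """Eluted-dye absorbance normalized to protein content (A500 / protein)."""
    protein = np.asarray(protein, dtype=float)
    if (protein <= 0).any():
        raise ValueError("protein content must be positive")
    out = np.asarray(a500, dtype=float) / protein
    return float(out) if out.ndim == 0 else out
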