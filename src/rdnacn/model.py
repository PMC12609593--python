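"""Cohort-level model object: descriptives, comparisons, and regression.

`CohortModel` wraps a master per-sample table (one row per donor sample
with absolute CN, active CN, methylation %, semen parameters, age, BMI,
semen class, pregnancy outcome).  ``fit()`` returns a
:class:`CohortResults` carrying group summaries, Mann-Whitney group
comparisons, Spearman correlations, normality checks, the minimum-CN
analysis, and the confounder-adjusted logistic pregnancy models, with a
``summary()`` text table and box-plot helpers.

``CohortModel.from_simulation`` runs the entire synthetic pipeline
(cohort -> droplets -> ddPCR estimates -> bisulfite reads -> methylation
profiles -> master table), attaching the generator truth for calibration
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import dbs, ddpcr, stats, synth
from ._util import child_seed
from .integrate import build_master_table
from .reference import AmpliconReference, default_reference

#: variables summarised per group, in the order of the printed tables
SUMMARY_VARIABLES = (
    "absolute_cn", "active_cn", "methylation_pct", "age", "bmi",
    "volume_ml", "conc_mio_per_ml", "morphology_pct", "motility_pct",
)

CORRELATION_PAIRS = tuple(
    (cn_var, other)
    for cn_var in ("active_cn", "absolute_cn")
    for other in ("conc_mio_per_ml", "motility_pct", "morphology_pct", "age", "bmi")
)


class CohortModel:
    """Cohort statistics model over a master per-sample table."""

    def __init__(
        self,
        data: pd.DataFrame,
        alpha: float = 0.05,
        k_minima: int = 5,
        standardize: bool = True,
        truth: pd.DataFrame | None = None,
    ):
        required = {"sample_id", "absolute_cn", "active_cn", "methylation_pct",
                    "semen_class", "pregnancy"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"master table missing columns: {sorted(missing)}")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.data = data.reset_index(drop=True)
        self.alpha = alpha
        self.k_minima = k_minima
        self.standardize = standardize
        self.truth = truth

    # ------------------------------------------------------------ constructors

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CohortModel":
        return cls(df, **kwargs)

    @classmethod
    def from_simulation(
        cls,
        spec: synth.CohortSpec | None = None,
        seed: int = 0,
        n_reads: int = 600,
        n_droplets: int = 20_000,
        ref_lambda: float = 0.0305,
        dilution_target: float = 10.0,
        conversion_failure_rate: float = 0.005,
        seq_error_rate: float = 0.001,
        minor_allele_fraction: float = 0.03,
        reference: AmpliconReference | None = None,
        m_ref: float = 1.0,
        call_options: dbs.CallOptions | None = None,
        **kwargs,
    ) -> "CohortModel":
        """Generate a cohort and push it through the full analysis pipeline."""
        spec = spec or synth.CohortSpec()
        ref = reference or default_reference()
        donors, sheet = synth.simulate_cohort(spec, seed=seed)
        counts = synth.droplet_counts_frame(
            donors, seed=seed, n_droplets=n_droplets,
            ref_lambda=ref_lambda, dilution_target=dilution_target,
        )
        cn_table = ddpcr.copy_numbers_from_counts(counts, m_ref=m_ref)
        opts = call_options or dbs.CallOptions()
        prof_rows = []
        for donor in donors:
            sim = synth.simulate_reads(
                donor, ref, n_reads=n_reads,
                conversion_failure_rate=conversion_failure_rate,
                seq_error_rate=seq_error_rate,
                minor_allele_fraction=minor_allele_fraction,
                seed=child_seed(seed, "sample_reads", donor.sample_id),
                mode_concentration=spec.mode_concentration,
            )
            pairs = _fastq_pairs(sim.fastq_r1, sim.fastq_r2)
            calls = dbs.call_reads(pairs, ref, opts)
            prof_rows.append(dbs.profile_sample(calls, donor.sample_id).to_row())
        profiles = pd.DataFrame(prof_rows)
        master = build_master_table(cn_table, profiles, sheet)
        return cls(master, truth=synth.truth_frame(donors), **kwargs)

    # ------------------------------------------------------------------- fit

    def fit(self) -> "CohortResults":
        df = self.data
        groupings = {
            "NSP": df["semen_class"] == "NSP",
            "ASP": df["semen_class"] == "ASP",
            "pregnancy": df["pregnancy"] == "yes",
            "no_pregnancy": df["pregnancy"] == "no",
        }
        variables = [v for v in SUMMARY_VARIABLES if v in df.columns]

        summaries = []
        for gname, mask in groupings.items():
            sub = df.loc[mask]
            for var in variables:
                vals = sub[var].dropna()
                if vals.empty:
                    continue
                row = stats.descriptive_summary(vals).to_row()
                summaries.append({"group": gname, "variable": var, **row})
        group_summaries = pd.DataFrame(summaries).set_index(["group", "variable"])

        comparisons = []
        for label, (ga, gb) in {
            "NSP_vs_ASP": ("NSP", "ASP"),
            "pregnancy_vs_no": ("pregnancy", "no_pregnancy"),
        }.items():
            a_mask, b_mask = groupings[ga], groupings[gb]
            for var in variables:
                a = df.loc[a_mask, var].dropna()
                b = df.loc[b_mask, var].dropna()
                if a.empty or b.empty:
                    continue
                res = stats.mann_whitney_u(a, b, method="asymptotic")
                comparisons.append({
                    "comparison": label, "variable": var, "U": res.statistic,
                    "n_a": res.n[0], "n_b": res.n[1], "p": res.p_value,
                    "method": res.method,
                    "significant": res.p_value <= self.alpha,
                })
        comparisons = pd.DataFrame(comparisons)

        correlations = []
        for xvar, yvar in CORRELATION_PAIRS:
            if xvar not in df.columns or yvar not in df.columns:
                continue
            try:
                res = stats.spearman_rho(df[xvar], df[yvar])
            except ValueError:
                continue
            correlations.append({
                "x": xvar, "y": yvar, "rho": res.statistic, "n": res.n[0],
                "p": res.p_value, "significant": (res.p_value <= self.alpha)
                if np.isfinite(res.p_value) else False,
            })
        correlations = pd.DataFrame(correlations)

        normality = []
        for var in variables:
            vals = df[var].dropna()
            if len(vals) < 3 or vals.nunique() == 1:
                continue
            ks, sw = stats.normality_tests(vals)
            normality.append({"variable": var, "ks_lilliefors_stat": ks.statistic,
                              "ks_lilliefors_p": ks.p_value,
                              "shapiro_stat": sw.statistic, "shapiro_p": sw.p_value})
        normality = pd.DataFrame(normality)

        regressions = {}
        for cn_var in ("absolute_cn", "active_cn"):
            try:
                regressions[cn_var] = stats.pregnancy_regression(
                    df, cn_variable=cn_var, standardize=self.standardize)
            except ValueError:
                pass

        try:
            minima = stats.minimum_cn_analysis(df, k=self.k_minima)
        except ValueError:
            minima = None

        return CohortResults(
            model=self,
            group_summaries=group_summaries,
            comparisons=comparisons,
            correlations=correlations,
            normality=normality,
            regressions=regressions,
            minima=minima,
        )


def _fastq_pairs(fastq_r1: str, fastq_r2: str | None):
    """(read_id, seq1[, seq2]) tuples from in-memory FASTQ text."""
    def parse(text):
        out = []
        lines = text.splitlines()
        for i in range(0, len(lines) - 3, 4):
            rid = lines[i][1:].split("/")[0].split()[0]
            out.append((rid, lines[i + 1]))
        return out

    r1 = parse(fastq_r1)
    if fastq_r2 is None:
        return r1
    r2 = dict(parse(fastq_r2))
    return [(rid, seq1, r2[rid]) for rid, seq1 in r1]


@dataclass
class CohortResults:
    """Fitted cohort statistics with a printable summary."""

    model: CohortModel
    group_summaries: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    normality: pd.DataFrame
    regressions: dict[str, stats.RegressionResult]
    minima: stats.MinimumCnResult | None

    def group_summary(self, group: str, variable: str) -> pd.Series:
        return self.group_summaries.loc[(group, variable)]

    def comparison_p(self, comparison: str, variable: str) -> float:
        sel = self.comparisons.query("comparison == @comparison and variable == @variable")
        if sel.empty:
            raise KeyError((comparison, variable))
        return float(sel["p"].iloc[0])

    def correlation(self, x: str, y: str) -> float:
        sel = self.correlations.query("x == @x and y == @y")
        if sel.empty:
            raise KeyError((x, y))
        return float(sel["rho"].iloc[0])

    def summary(self) -> str:
        lines = ["Sperm rDNA copy-number cohort analysis", "=" * 54]
        n = len(self.model.data)
        n_nsp = int((self.model.data["semen_class"] == "NSP").sum())
        n_asp = int((self.model.data["semen_class"] == "ASP").sum())
        lines.append(f"Samples: {n} (NSP {n_nsp}, ASP {n_asp})")
        lines.append("")
        for group in ("NSP", "ASP", "pregnancy", "no_pregnancy"):
            if group not in self.group_summaries.index.get_level_values(0):
                continue
            sub = self.group_summaries.loc[group]
            lines.append(f"[{group}]  (n = {int(sub['n'].iloc[0])})")
            for var, row in sub.iterrows():
                lines.append(
                    f"  {var:<18} {row['mean']:8.1f} ± {row['sd']:5.1f}   "
                    f"median {row['median']:7.1f}   range {row['min']:.1f}–{row['max']:.1f}"
                )
            lines.append("")
        if not self.comparisons.empty:
            lines.append("Mann–Whitney group comparisons (asymptotic, tie-corrected):")
            for _, r in self.comparisons.iterrows():
                star = " *" if r["significant"] else ""
                lines.append(f"  {r['comparison']:<18} {r['variable']:<18} "
                             f"U = {r['U']:9.1f}   p = {r['p']:.4g}{star}")
            lines.append("")
        if not self.correlations.empty:
            lines.append("Spearman correlations:")
            for _, r in self.correlations.iterrows():
                star = " *" if r["significant"] else ""
                lines.append(f"  {r['x']:<14} vs {r['y']:<16} rho = {r['rho']:+.3f}   "
                             f"p = {r['p']:.4g}{star}")
            lines.append("")
        for cn_var, reg in self.regressions.items():
            flag = "" if reg.converged else "  [not converged]"
            lines.append(f"Logistic pregnancy model ({cn_var}, n = {reg.n}){flag}:")
            for name, row in reg.table.iterrows():
                lines.append(f"  {name:<18} coef = {row['coef']:+.3f}  "
                             f"se = {row['se']:.3f}  p = {row['p']:.4g}")
            lines.append("")
        if self.minima is not None:
            m = self.minima
            lines.append(f"Lowest {m.k} active CNs overall:   "
                         + ", ".join(f"{v:.0f}" for v in m.overall_minima))
            lines.append(f"Lowest {m.k} with pregnancy:      "
                         + ", ".join(f"{v:.0f}" for v in m.pregnancy_minima))
            if m.comparison is not None:
                lines.append(f"  Mann–Whitney ({m.comparison.method}) p = {m.comparison.p_value:.4g}; "
                             f"empirical floor with pregnancy = {m.floor:.0f} copies")
        return "\n".join(lines)

    # ------------------------------------------------------------------ plots

    def plot_group_boxplots(self, variable: str = "active_cn",
                            by: str = "semen_class", ax=None):
        """Box plot of one variable by group (semen class or pregnancy)."""
        import matplotlib.pyplot as plt

        df = self.model.data
        order = ["NSP", "ASP"] if by == "semen_class" else ["yes", "no"]
        groups = [df.loc[df[by] == g, variable].dropna() for g in order]
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.boxplot(groups, tick_labels=order)
        ax.set_ylabel(variable)
        ax.set_xlabel(by)
        return ax
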