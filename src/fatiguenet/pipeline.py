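"""End-to-end study orchestration.

``run_study`` reproduces the full analysis sequence on a cohort of paired
recordings: whole-brain band power per subject and condition, paired
band-power statistics with a Kolmogorov–Smirnov normality gate
(Bonferroni family of 3), selection of the most fatigue-sensitive band by
effect-size magnitude, phase-lag connectivity matrices in that band,
proportional thresholding, global and regional network metrics, their
paired statistics (Shapiro–Wilk gates; Bonferroni families of 5 global
and 10 local tests), and Spearman correlations between metric changes and
the VAS-F total score.

Regions with three or fewer channels skip the normality evaluation (the
convention for N ≤ 3 samples) and are routed to the signed-rank branch.
All randomness (null-network surrogates) derives from one root seed via
named substreams, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graphmetrics, spectral, stats
from .connectivity import connectivity_matrix
from .montage import Montage, REGION_ORDER, default_montage
from .spectral import BANDS, get_band

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "StudyReport",
    "select_sensitive_band",
    "run_study",
]

GLOBAL_METRICS = ("Eg", "Eloc", "Cp", "Lp", "Sigma")
LOCAL_METRICS = ("NE", "DC")
#: Regions whose metric-change correlations with VAS-F are reported.
CORRELATION_REGIONS = ("frontal", "parietal", "central", "centro-parietal")


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name and subject."""


@dataclass
class PipelineConfig:
    """Parameters of one study run."""

    estimator: str = "paper_formula"
    segment_seconds: float = 2.0        # Welch segment length
    overlap_fraction: float = 0.5
    test_proportion: float = 0.25       # sparsity at which statistics run
    proportions: tuple[float, ...] = graphmetrics.DEFAULT_PROPORTIONS
    run_sweep: bool = False             # also compute threshold-sweep curves
    n_null: int = 100                   # surrogates for Sigma
    alpha: float = 0.05
    m_bands: int = 3
    m_global: int = 5
    m_local: int = 10
    wilcoxon_r: str = "z_over_sqrt_n"
    seed: int = 0
    output_dir: str | None = None
    write_matrices: bool = False

    def __post_init__(self) -> None:
        for m in (self.m_bands, self.m_global, self.m_local):
            if m < 1:
                raise ValueError("family sizes must be positive")


@dataclass
class StudyReport:
    """Everything one study run produced."""

    band_table: pd.DataFrame
    band_tests: dict[str, stats.TestResult]
    selected_band: str
    global_table: pd.DataFrame
    local_table: pd.DataFrame
    global_tests: dict[str, stats.TestResult]
    local_tests: dict[tuple[str, str], stats.TestResult]
    correlations: pd.DataFrame
    vasf_total: pd.DataFrame
    params: dict
    sweep: pd.DataFrame | None = None

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for band, t in self.band_tests.items():
            rows.append({"family": "band", "metric": "PSD", "region": band, **_row(t)})
        for metric, t in self.global_tests.items():
            rows.append({"family": "global", "metric": metric, "region": "", **_row(t)})
        for (metric, region), t in self.local_tests.items():
            rows.append({"family": "local", "metric": metric, "region": region, **_row(t)})
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Human-readable report mirroring the regional-table layout."""
        lines = [f"Selected band: {self.selected_band}", "", "Band power (whole-brain mean, log10):"]
        for band, t in self.band_tests.items():
            lines.append(_fmt_row(band, t))
        lines += ["", f"Global metrics ({self.selected_band} band, "
                      f"proportion {self.params['test_proportion']}):"]
        for metric, t in self.global_tests.items():
            lines.append(_fmt_row(metric, t))
        for metric in LOCAL_METRICS:
            lines += ["", f"Regional {metric}:"]
            for (m, region), t in self.local_tests.items():
                if m == metric:
                    lines.append(_fmt_row(region, t))
        lines += ["", "Spearman correlation with VAS-F total change:"]
        for _, row in self.correlations.iterrows():
            lines.append(f"  {row['metric']:<24} rho={row['rho']:+.3f}  p={row['p']:.3f}")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.band_table.to_csv(out_dir / "band_table.csv", index=False)
        self.global_table.to_csv(out_dir / "metrics_global.csv", index=False)
        self.local_table.to_csv(out_dir / "metrics_local.csv", index=False)
        self.tests_frame().to_csv(out_dir / "tests.csv", index=False)
        self.correlations.to_csv(out_dir / "correlations.csv", index=False)
        if self.sweep is not None:
            self.sweep.to_csv(out_dir / "threshold_sweep.csv", index=False)
        (out_dir / "report.txt").write_text(self.to_text() + "\n")
        (out_dir / "run_log.json").write_text(json.dumps(self.params, indent=1,
                                                         default=str))
        return out_dir


def _row(t: stats.TestResult) -> dict:
    return {"test": t.test, "p": t.p, "statistic": t.statistic, "d": t.d,
            "r": t.r, "normality_p": t.normality_p,
            "alpha_adjusted": t.significant_at, "significant": t.significant,
            "mean_pre": t.mean_pre, "sd_pre": t.sd_pre,
            "mean_post": t.mean_post, "sd_post": t.sd_post}


def _fmt_row(label: str, t: stats.TestResult) -> str:
    norm = f"{t.normality_p:.3f}" if np.isfinite(t.normality_p) else "—"
    star = " *" if t.significant else ""
    return (f"  {label:<18} pre {t.mean_pre:8.3f} ± {t.sd_pre:6.3f}   "
            f"post {t.mean_post:8.3f} ± {t.sd_post:6.3f}   "
            f"S-W/K-S p={norm:<6} {t.test:<8} p={t.p:.4g} r={t.r:+.2f}{star}")


def select_sensitive_band(band_tests: dict[str, stats.TestResult]) -> str:
    """Band with the largest |r| effect size; ties break in θ < α < β order."""
    if not band_tests:
        raise ValueError("no band results supplied")
    order = [b.name for b in BANDS]
    names = sorted(band_tests, key=lambda n: order.index(n) if n in order else 99)
    best = max(names, key=lambda n: abs(band_tests[n].r))
    ties = [n for n in names if abs(band_tests[n].r) == abs(band_tests[best].r)]
    if len(ties) > 1:
        warnings.warn(
            f"effect-size tie between bands {ties}; keeping {ties[0]!r} "
            "(fixed θ<α<β order)")
        best = ties[0]
    return best


def _paired_from_table(table: pd.DataFrame, value_col: str, subjects,
                       label: str) -> stats.PairedSample:
    pre = table[table.condition == "pre"].set_index("subject")[value_col]
    post = table[table.condition == "post"].set_index("subject")[value_col]
    return stats.PairedSample(pre=pre.loc[list(subjects)].to_numpy(),
                              post=post.loc[list(subjects)].to_numpy(),
                              label=label)


def _null_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(4, *key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_study(cohort, config: PipelineConfig | None = None,
              montage: Montage | None = None) -> StudyReport:
    """Run the full pre/post analysis on a cohort.

    ``cohort`` exposes ``subjects``, ``conditions`` (must include "pre" and
    "post"), ``recording(subject, condition)`` and a ``vasf`` frame with
    columns ``subject, condition, fatigue, energy``.
    """
    config = config or PipelineConfig()
    montage = montage or default_montage()
    subjects = list(cohort.subjects)

    # --- stage 1: band power -------------------------------------------------
    try:
        seg = None
        if config.segment_seconds is not None:
            fs = cohort.recording(subjects[0], "pre").fs
            seg = int(round(config.segment_seconds * fs))
        band_table = spectral.cohort_band_table(
            cohort, segment_length=seg,
            overlap_fraction=config.overlap_fraction, montage=montage)
    except Exception as e:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(f"stage=band_power: {e}") from e

    alpha_bands = stats.bonferroni(config.alpha, config.m_bands)
    band_tests: dict[str, stats.TestResult] = {}
    for band in BANDS:
        sub = band_table[band_table.band == band.name]
        sample = _paired_from_table(sub, "value", subjects, f"PSD[{band.name}]")
        gate = stats.normality_gate(sample.differences, method="ks")
        band_tests[band.name] = stats.paired_test(
            sample, gate, significant_at=alpha_bands,
            wilcoxon_r=config.wilcoxon_r)
    selected = select_sensitive_band(band_tests)

    # --- stage 2: connectivity + graph metrics -------------------------------
    g_rows, l_rows = [], []
    mean_weights = {"pre": None, "post": None}
    out_dir = Path(config.output_dir) if config.output_dir else None
    for subject in subjects:
        for condition in ("pre", "post"):
            try:
                rec = cohort.recording(subject, condition)
                conn = connectivity_matrix(rec, get_band(selected),
                                           estimator=config.estimator,
                                           montage=montage)
                if config.run_sweep:
                    prev = mean_weights[condition]
                    mean_weights[condition] = (
                        conn.weights if prev is None else prev + conn.weights)
                if config.write_matrices and out_dir is not None:
                    from .io import write_matrix

                    mdir = out_dir / "matrices"
                    mdir.mkdir(parents=True, exist_ok=True)
                    write_matrix(conn.weights, conn.channels,
                                 mdir / f"sub-{subject}_{condition}_{selected}.tsv")
                net = graphmetrics.proportional_threshold(
                    conn, config.test_proportion)
                cond_idx = 0 if condition == "pre" else 1
                gm = graphmetrics.global_metrics(
                    net, n_null=config.n_null,
                    null_seed=_null_seed(config.seed, int(subject), cond_idx))
                nm = graphmetrics.nodal_metrics(net, montage)
            except Exception as e:  # noqa: BLE001
                raise PipelineError(
                    f"stage=network_metrics, subject={subject}, "
                    f"condition={condition}: {e}") from e
            for metric, value in gm.as_dict().items():
                g_rows.append({"subject": subject, "condition": condition,
                               "proportion": config.test_proportion,
                               "metric": metric, "value": value})
            for region, row in nm.region_means.iterrows():
                for metric in LOCAL_METRICS:
                    l_rows.append({"subject": subject, "condition": condition,
                                   "proportion": config.test_proportion,
                                   "metric": metric, "region": region,
                                   "value": row[metric]})
    global_table = pd.DataFrame(g_rows)
    local_table = pd.DataFrame(l_rows)

    # --- stage 3: network statistics ----------------------------------------
    alpha_global = stats.bonferroni(config.alpha, config.m_global)
    global_tests: dict[str, stats.TestResult] = {}
    for metric in GLOBAL_METRICS:
        sub = global_table[global_table.metric == metric]
        sample = _paired_from_table(sub, "value", subjects, metric)
        gate = stats.normality_gate(sample.differences, method="shapiro")
        global_tests[metric] = stats.paired_test(
            sample, gate, significant_at=alpha_global,
            wilcoxon_r=config.wilcoxon_r)

    alpha_local = stats.bonferroni(config.alpha, config.m_local)
    local_tests: dict[tuple[str, str], stats.TestResult] = {}
    for metric in LOCAL_METRICS:
        for region in REGION_ORDER:
            sub = local_table[(local_table.metric == metric)
                              & (local_table.region == region)]
            if sub.empty:
                continue
            sample = _paired_from_table(sub, "value", subjects,
                                        f"{metric}[{region}]")
            if len(montage.regions[region]) <= 3:
                # region too small to evaluate normality; nonparametric branch
                gate = stats.NormalityResult(p=float("nan"), is_normal=None,
                                             evaluated=False, method="shapiro")
            else:
                gate = stats.normality_gate(sample.differences, method="shapiro")
            local_tests[(metric, region)] = stats.paired_test(
                sample, gate, significant_at=alpha_local,
                wilcoxon_r=config.wilcoxon_r)

    # --- stage 4: correlation with subjective fatigue ------------------------
    vasf = cohort.vasf.copy()
    vasf["total"] = (vasf["fatigue"] + (100.0 - vasf["energy"])) / 2.0
    total = _paired_from_table(vasf, "total", subjects, "VAS-F total")
    corr_rows = []
    for metric in ("Eg", "Eloc", "Lp", "Cp"):
        sample = _paired_from_table(global_table[global_table.metric == metric],
                                    "value", subjects, metric)
        rho, p = stats.spearman(sample.differences, total.differences)
        corr_rows.append({"metric": metric, "rho": rho, "p": p})
    for region in CORRELATION_REGIONS:
        sub = local_table[(local_table.metric == "NE")
                          & (local_table.region == region)]
        sample = _paired_from_table(sub, "value", subjects, f"NE[{region}]")
        rho, p = stats.spearman(sample.differences, total.differences)
        corr_rows.append({"metric": f"NE[{region}]", "rho": rho, "p": p})
    correlations = pd.DataFrame(corr_rows)

    sweep = None
    if config.run_sweep:
        frames = []
        for condition, acc in mean_weights.items():
            df = graphmetrics.threshold_sweep(
                acc / len(subjects), config.proportions,
                n_null=config.n_null, null_seed=_null_seed(config.seed, 5))
            df.insert(0, "condition", condition)
            frames.append(df)
        sweep = pd.concat(frames, ignore_index=True)

    params = {
        "estimator": config.estimator,
        "segment_seconds": config.segment_seconds,
        "overlap_fraction": config.overlap_fraction,
        "test_proportion": config.test_proportion,
        "n_null": config.n_null,
        "alpha": config.alpha,
        "alpha_adjusted": {"bands": alpha_bands, "global": alpha_global,
                           "local": alpha_local},
        "wilcoxon_r": config.wilcoxon_r,
        "seed": config.seed,
        "selected_band": selected,
        "n_subjects": len(subjects),
    }
    report = StudyReport(
        band_table=band_table, band_tests=band_tests, selected_band=selected,
        global_table=global_table, local_table=local_table,
        global_tests=global_tests, local_tests=local_tests,
        correlations=correlations, vasf_total=vasf, params=params, sweep=sweep)
    if out_dir is not None:
        report.write(out_dir)
    return report
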