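"""Statistical layer: per-mode summaries, repeated-measures comparison and
the exponential wasted-effort regression.

Ventilation modes recorded within the same subjects are compared with the
Friedman test (nonparametric repeated measures) followed by Dunn's post hoc
pairwise comparisons on the Friedman rank sums. Normality is assessed with
the D'Agostino-Pearson omnibus K² test. The relationship between
dyssynchrony and wasted efforts is modelled as y = a·exp(b·x), fitted by
nonlinear least squares in the original y-space with a log-linear
initialization, where x is the NeuroSync index recomputed without wasted
efforts (so the two axes are not mathematically coupled).

Summaries are reported as median (IQR), the convention for these
physiological variables; means ± SD appear only for absolute cycling-off
milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError, QualityError
from .event_detection import DetectorParams
from .pipeline import AnalysisResult, analyze_recording
from .synchrony_core import SynchronyParams
from .waveform_io import Recording


@dataclass
class ModeResult:
    """One ventilation mode's analysis plus breathing-pattern medians."""

    mode_label: str
    analysis: AnalysisResult
    pattern: dict  # medians over breaths: peak EAdi, peak Paw, peak flow, neural RR

    @property
    def report(self):
        return self.analysis.report


def summarize_mode(
    rec: Recording,
    window_s: float = 300.0,
    mode_label: str | None = None,
    det_params: DetectorParams | None = None,
    syn_params: SynchronyParams | None = None,
    min_median_peak_uV: float = 1.0,
) -> ModeResult:
    """Analyze one mode's recording; refuse recordings failing the quality gate."""
    result = analyze_recording(
        rec, window_s=window_s, det_params=det_params, syn_params=syn_params,
        min_median_peak_uV=min_median_peak_uV,
    )
    if not result.quality.ok:
        raise QualityError(result.quality)
    med = lambda xs: float(np.median(xs)) if len(xs) else float("nan")
    flows = [v.peak_flow_lmin for v in result.vent_breaths if v.peak_flow_lmin is not None]
    pattern = {
        "peak_eadi_uV": med([b.peak_uV for b in result.neural_breaths]),
        "peak_paw_cmH2O": med([v.peak_paw_cmH2O for v in result.vent_breaths]),
        "peak_flow_lmin": med(flows),
        "neural_rr_bpm": result.neural_rr_bpm,
    }
    return ModeResult(
        mode_label=mode_label or str(rec.meta.get("mode", "unknown")),
        analysis=result,
        pattern=pattern,
    )


# ---------------------------------------------------------------------------
# repeated-measures statistics
# ---------------------------------------------------------------------------

@dataclass
class DunnComparison:
    mode_a: str
    mode_b: str
    z: float
    p: float
    significant: bool


@dataclass
class FriedmanResult:
    statistic: float
    pvalue: float
    n_subjects: int
    modes: List[str]
    rank_sums: List[float]
    dunn: List[DunnComparison] = field(default_factory=list)


def compare_modes(
    per_subject: Sequence[Tuple[str, str, float]],
    alpha: float = 0.05,
) -> FriedmanResult:
    """Friedman test with Dunn's post hoc across paired conditions.

    ``per_subject`` holds (subject, mode, value) triples; every subject must
    contribute one value per mode (complete blocks) and at least 3 subjects
    are required. Dunn's pairwise z uses the Friedman rank sums with the
    customary variance n·k·(k+1)/6 and a Bonferroni-adjusted critical level
    over the k(k-1)/2 pairs (Dunn's correction).
    """
    modes = sorted({m for _, m, _ in per_subject})
    subjects = sorted({s for s, _, _ in per_subject})
    k, n = len(modes), len(subjects)
    if n < 3:
        raise ConfigError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ConfigError("need at least 2 modes")
    table = {}
    for s, m, v in per_subject:
        if (s, m) in table:
            raise ConfigError(f"duplicate value for subject {s!r}, mode {m!r}")
        table[(s, m)] = float(v)
    for s in subjects:
        missing = [m for m in modes if (s, m) not in table]
        if missing:
            raise ConfigError(f"incomplete block: subject {s!r} lacks modes {missing}")

    data = np.array([[table[(s, m)] for m in modes] for s in subjects])
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)

    if np.allclose(ranks.var(axis=1), 0.0):
        stat, p = 0.0, 1.0  # every block fully tied: no evidence of ordering
    else:
        stat, p = sps.friedmanchisquare(*[data[:, j] for j in range(k)])

    crit = alpha / (k * (k - 1) / 2.0)
    se = np.sqrt(n * k * (k + 1) / 6.0)
    dunn = []
    for a in range(k):
        for b in range(a + 1, k):
            z = (rank_sums[a] - rank_sums[b]) / se
            p_ab = 2.0 * sps.norm.sf(abs(z))
            dunn.append(DunnComparison(modes[a], modes[b], float(z), float(p_ab),
                                       bool(p_ab < crit)))
    return FriedmanResult(float(stat), float(p), n, modes,
                          [float(r) for r in rank_sums], dunn)


def test_normality(values: Sequence[float]) -> Tuple[float, float]:
    """D'Agostino-Pearson omnibus K² normality test (requires n >= 8)."""
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ConfigError(f"normality test requires n >= 8, got {values.size}")
    stat, p = sps.normaltest(values)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# exponential least-squares regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    a: float
    b: float
    r2: float
    n: int
    degenerate: bool = False


def fit_exponential(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Least-squares fit of y = a·exp(b·x) in original y-space.

    Initialized from the log-linear regression on the y > 0 points, then
    refined by nonlinear least squares (so large-y points are not
    down-weighted as a pure log fit would). r² is computed against the
    mean-y baseline.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigError("x and y must have equal length")
    if x.size < 3:
        raise ConfigError(f"exponential fit requires >= 3 points, got {x.size}")
    pos = y > 0
    if not np.any(pos):
        return RegressionFit(0.0, 0.0, float("nan"), int(x.size), degenerate=True)
    if pos.sum() >= 2:
        b0, loga0 = np.polyfit(x[pos], np.log(y[pos]), 1)
        a0 = float(np.exp(loga0))
    else:
        a0, b0 = float(y[pos][0]), 0.0
    try:
        (a, b), _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                              p0=[a0, b0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    resid = y - a * np.exp(b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return RegressionFit(float(a), float(b), r2, int(x.size))


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _iqr_str(values) -> str:
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(np.isnan(v)):
        return "n/a"
    return f"{np.nanmedian(v):.1f} ({np.nanpercentile(v, 25):.1f} - {np.nanpercentile(v, 75):.1f})"


def render_report(
    results: List[ModeResult],
    out_dir,
    friedman: FriedmanResult | None = None,
    regression: RegressionFit | None = None,
) -> dict:
    """Write ``summary.json`` and ``summary.txt`` for one or more modes.

    The JSON carries every computed quantity (pattern medians, NeuroSync
    indices, event counts, proportions, density grids, per-breath tables,
    statistics) plus full parameter provenance; the text file is a compact
    human-readable digest.
    """
    if not results:
        raise ConfigError("render_report needs at least one ModeResult")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = {"modes": {}}
    for mr in results:
        summary["modes"][mr.mode_label] = {
            "pattern": mr.pattern,
            "quality": vars(mr.analysis.quality),
            "report": mr.report.to_dict(),
        }
    if friedman is not None:
        summary["friedman"] = {
            "statistic": friedman.statistic,
            "pvalue": friedman.pvalue,
            "n_subjects": friedman.n_subjects,
            "modes": friedman.modes,
            "rank_sums": friedman.rank_sums,
            "dunn": [vars(d) for d in friedman.dunn],
        }
    if regression is not None:
        summary["regression"] = vars(regression)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))

    lines = ["Patient-ventilator interaction summary", "=" * 40, ""]
    for mr in results:
        rep = mr.report
        matched = [r for r in rep.per_breath if r.klass == "matched"]
        lines += [
            f"Mode: {mr.mode_label}",
            f"  breaths analyzed        : {rep.n_breaths}",
            f"  NeuroSync index         : {rep.neurosync_pct:.1f} %"
            if rep.neurosync_pct is not None else "  NeuroSync index         : n/a",
            f"  (without wasted efforts): {rep.neurosync_no_wasted_pct:.1f} %"
            if rep.neurosync_no_wasted_pct is not None else "",
            f"  synchronous / dyssynchronous / asynchronous: "
            f"{rep.pct_synchronous:.1f} / {rep.pct_dyssynchronous:.1f} / "
            f"{rep.pct_asynchronous:.1f} %",
            f"  trigger delay (ms)      : "
            + _iqr_str([r.trigger_delay_ms for r in matched if r.trigger_delay_ms is not None]),
            f"  cycling-off error (ms)  : "
            + _iqr_str([r.cycleoff_error_ms for r in matched if r.cycleoff_error_ms is not None]),
            f"  wasted efforts /min     : {rep.wasted_per_min:.2f}",
            f"  peak EAdi (uV)          : {mr.pattern['peak_eadi_uV']:.1f}",
            f"  peak Paw (cmH2O)        : {mr.pattern['peak_paw_cmH2O']:.1f}",
            f"  neural RR (breaths/min) : {mr.pattern['neural_rr_bpm']:.1f}",
            "",
        ]
    if friedman is not None:
        lines += [f"Friedman: chi2={friedman.statistic:.3f}, p={friedman.pvalue:.4g}"]
        for d in friedman.dunn:
            mark = "*" if d.significant else " "
            lines.append(f"  {d.mode_a} vs {d.mode_b}: z={d.z:+.2f}, p={d.p:.4g} {mark}")
    if regression is not None:
        lines.append(
            f"Exponential fit: y = {regression.a:.3g} * exp({regression.b:.3g} x), "
            f"r2 = {regression.r2:.3f} (n={regression.n})"
        )
    (out_dir / "summary.txt").write_text("\n".join(line for line in lines if line != ""))
    return summary
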