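"""The core workflow: per-fraction structure transfer into the planning
frame, daily DVH evaluation against the planned dose, accumulation over the
course, deviation computation and relevance flagging.

Accumulation model
------------------
The estimator assumes each session delivers 1/N of the plan to the daily
anatomy and that volume fractions are exchangeable across sessions; the
accumulated cumulative DVH is then the equal-weight mean of the daily
cumulative relative-volume DVHs on a common dose axis (in plan-total Gy,
so session curves overlay the baseline directly).  Accumulated Dmean and
VxGy are means of the per-fraction values (exact under the same model);
accumulated dose percentiles (D98/D50/D2) are read from a fine-binned
(0.01 Gy) mixture histogram of the per-fraction dose samples, which is the
same estimate at negligible discretisation cost.  Partial courses use the
available-fraction mean and report ``n_available``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .core import FractionRecord, TreatmentCourse
from .dvh import (
    DoseMetrics,
    DoseSamples,
    DvhCurve,
    compute_metrics,
    cumulative_dvh,
    sample_dose,
)
from .errors import ConfigError, DoseAccumError, LookupError_
from .geometry import (
    BinaryMask,
    GeometrySummary,
    expand_margin,
    isotropic_geometry,
    rasterize,
    summarize_geometry,
    transform_roi,
)

__all__ = [
    "Baseline",
    "FractionResult",
    "AccumulatedResult",
    "CourseReport",
    "evaluate_baseline",
    "evaluate_fraction",
    "accumulate",
    "threshold_exceedance_rate",
    "run_course",
]

log = logging.getLogger("doseaccum")

METRIC_NAMES = DoseMetrics._FIELDS


@dataclass
class _FineHist:
    """Fixed-grid histogram of one fraction's dose samples (for pooling)."""

    edges: np.ndarray
    counts: np.ndarray
    n: int


def _fine_hist(values: np.ndarray, edges: np.ndarray) -> _FineHist:
    # uniform bins: direct index + bincount is much faster than np.histogram
    width = edges[1] - edges[0]
    idx = np.clip((values / width).astype(np.int64), 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return _FineHist(edges=edges, counts=counts, n=values.size)


@dataclass
class Baseline:
    """Metrics/curves of the planning structures on the planned dose."""

    metrics: dict[str, DoseMetrics]
    curves: dict[str, DvhCurve]
    masks: dict[str, BinaryMask]
    samples: dict[str, DoseSamples]
    eval_geometry: object
    dose_on_eval: np.ndarray | None = None  # plan dose on the eval grid
    hists: dict[str, _FineHist] = field(default_factory=dict, repr=False)


@dataclass
class FractionResult:
    """One session's geometric and dosimetric evaluation vs baseline."""

    fraction_index: int
    geometry: dict[str, GeometrySummary]
    metrics: dict[str, DoseMetrics]
    curves: dict[str, DvhCurve]
    deviation_pct: dict[str, dict[str, float | None]]
    hists: dict[str, _FineHist] = field(default_factory=dict, repr=False)


@dataclass
class AccumulatedResult:
    """Course-level accumulated DVHs, metrics, deviations and flags."""

    metrics: dict[str, DoseMetrics]
    curves: dict[str, DvhCurve]
    deviation_pct: dict[str, dict[str, float | None]]
    relevant_flags: dict[str, dict[str, bool]]
    n_available: int
    n_planned: int


def _metric_deviations(daily: DoseMetrics, base: DoseMetrics
                       ) -> dict[str, float | None]:
    """Percent change of each metric normalised to the planned value.

    ``None`` (missing, not 0) when the planned value is zero.
    """
    out: dict[str, float | None] = {}
    for name in METRIC_NAMES:
        b = getattr(base, name)
        d = getattr(daily, name)
        out[name] = None if b == 0 else (d - b) / b * 100.0
    return out


def _structure_masks(structure_set, registration, config: RunConfig,
                     eval_geom) -> dict[str, BinaryMask]:
    """Transform requested ROIs into the planning frame and rasterize.

    ``registration`` is ``None`` for the planning set itself.  The
    prostate + margin target is regenerated from the (daily) prostate mask.
    """
    masks: dict[str, BinaryMask] = {}
    for name in config.structures:
        roi = structure_set.get(name)
        if registration is not None:
            roi = transform_roi(roi, registration, "moving_to_fixed")
        masks[name] = rasterize(roi, eval_geom, supersample=config.supersample)
    if config.prostate_name in masks:
        masks[config.target_name] = expand_margin(
            masks[config.prostate_name], config.margin_mm)
    return masks


def _evaluate_masks(masks, dose, config: RunConfig, dose_on_eval=None):
    """Dose samples, metrics, curves and fine histograms for each mask."""
    dmax = float(dose.values.max()) * 1.05 + config.fine_bin_width_gy
    edges = np.arange(0.0, dmax + config.fine_bin_width_gy,
                      config.fine_bin_width_gy)
    samples, metrics, curves, hists = {}, {}, {}, {}
    for name, mask in masks.items():
        s = sample_dose(mask, dose,
                        max_outside_fraction=config.max_outside_fraction,
                        dose_on_grid=dose_on_eval)
        s.structure = name
        samples[name] = s
        metrics[name] = compute_metrics(s)
        curves[name] = cumulative_dvh(s, config.bin_width_gy)
        hists[name] = _fine_hist(s.values, edges)
    return samples, metrics, curves, hists


def evaluate_baseline(course: TreatmentCourse,
                      config: RunConfig | None = None) -> Baseline:
    """Metrics and DVHs of the planning anatomy on the planned dose.

    Deterministic: repeated calls on the same course give identical
    results.  The prostate + 1 cm margin target is generated automatically.
    """
    config = config or RunConfig()
    for name in config.structures:
        if name not in course.planning_structures:
            raise LookupError_(
                f"structure {name!r} missing from planning set; available: "
                f"{sorted(course.planning_structures.rois)}")
    eval_geom = isotropic_geometry(course.plan_dose.geometry,
                                   config.geometry_spacing_mm)
    from .dvh import interpolate_on_geometry

    dose_on_eval = interpolate_on_geometry(course.plan_dose, eval_geom)
    masks = _structure_masks(course.planning_structures, None, config,
                             eval_geom)
    samples, metrics, curves, hists = _evaluate_masks(
        masks, course.plan_dose, config, dose_on_eval)
    return Baseline(metrics=metrics, curves=curves, masks=masks,
                    samples=samples, eval_geometry=eval_geom,
                    dose_on_eval=dose_on_eval, hists=hists)


def evaluate_fraction(course: TreatmentCourse, fraction: FractionRecord,
                      baseline: Baseline,
                      config: RunConfig | None = None) -> FractionResult:
    """Evaluate one session: transfer contours to the planning frame,
    compare geometry against baseline and compute daily DVH metrics in
    plan-total dose units."""
    config = config or RunConfig()
    try:
        masks = _structure_masks(fraction.structure_set,
                                 fraction.registration, config,
                                 baseline.eval_geometry)
        _, metrics, curves, hists = _evaluate_masks(
            masks, course.plan_dose, config, baseline.dose_on_eval)
        geometry = {name: summarize_geometry(masks[name],
                                             baseline.masks[name])
                    for name in masks}
        deviations = {name: _metric_deviations(metrics[name],
                                               baseline.metrics[name])
                      for name in metrics}
    except DoseAccumError as exc:
        raise type(exc)(f"fraction {fraction.index}: {exc}") from exc
    return FractionResult(fraction_index=fraction.index, geometry=geometry,
                          metrics=metrics, curves=curves,
                          deviation_pct=deviations, hists=hists)


def _mean_curve(curves: list[DvhCurve]) -> DvhCurve:
    widths = {round(c.bin_width_gy, 9) for c in curves}
    if len(widths) > 1:
        raise ConfigError(f"mixed DVH bin widths {sorted(widths)}")
    w = curves[0].bin_width_gy
    n_max = max(len(c.dose_axis) for c in curves)
    axis = np.arange(n_max) * w
    acc = np.zeros(n_max)
    for c in curves:
        padded = np.zeros(n_max)
        padded[:len(c.cum_volume_pct)] = c.cum_volume_pct
        acc += padded
    acc /= len(curves)
    return DvhCurve(dose_axis=axis, cum_volume_pct=acc,
                    structure=curves[0].structure,
                    total_volume_cm3=float(np.mean(
                        [c.total_volume_cm3 for c in curves])),
                    bin_width_gy=w)


def _hist_quantile(pdf: np.ndarray, edges: np.ndarray, q: float) -> float:
    """Quantile of a binned distribution, linear within the covering bin."""
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    k = int(np.searchsorted(cdf, q, side="left"))
    k = min(k, len(pdf) - 1)
    c_lo = cdf[k - 1] if k > 0 else 0.0
    c_hi = cdf[k]
    frac = 0.0 if c_hi == c_lo else (q - c_lo) / (c_hi - c_lo)
    return float(edges[k] + frac * (edges[k + 1] - edges[k]))


def accumulate(fraction_results: list[FractionResult], baseline: Baseline,
               n_planned: int,
               config: RunConfig | None = None) -> AccumulatedResult:
    """Pool the available sessions into the accumulated-course estimate.

    See the module docstring for the model.  Deviations are normalised to
    the planned (baseline) values; a metric whose planned value is zero
    gets a missing (``None``) deviation and no flag.  Invariant to the
    order of ``fraction_results``.
    """
    config = config or RunConfig()
    if not fraction_results:
        raise ConfigError("need at least one fraction result")
    # stable processing order makes the result exactly permutation-invariant
    fraction_results = sorted(fraction_results,
                              key=lambda fr: fr.fraction_index)
    names = list(fraction_results[0].metrics)

    curves: dict[str, DvhCurve] = {}
    metrics: dict[str, DoseMetrics] = {}
    for name in names:
        curves[name] = _mean_curve([fr.curves[name] for fr in fraction_results])
        # exact per-fraction means/volumes-at-dose; percentiles from the
        # pooled fine histogram (equal fraction weights)
        dmean = float(np.mean([fr.metrics[name].Dmean_Gy
                               for fr in fraction_results]))
        v20 = float(np.mean([fr.metrics[name].V20Gy_pct
                             for fr in fraction_results]))
        v50 = float(np.mean([fr.metrics[name].V50Gy_pct
                             for fr in fraction_results]))
        hists = [fr.hists[name] for fr in fraction_results]
        edges = max((h.edges for h in hists), key=len)
        pdf = np.zeros(len(edges) - 1)
        for h in hists:
            pdf[:len(h.counts)] += h.counts / h.n
        metrics[name] = DoseMetrics(
            D98_Gy=_hist_quantile(pdf, edges, 0.02),
            D50_Gy=_hist_quantile(pdf, edges, 0.50),
            D2_Gy=_hist_quantile(pdf, edges, 0.98),
            Dmean_Gy=dmean, V20Gy_pct=v20, V50Gy_pct=v50)

    # deviations compare like with like: the baseline dose percentiles are
    # re-read through the same fine-histogram estimator as the accumulated
    # ones, so an unchanged-anatomy course deviates by exactly zero (the
    # reported baseline metrics themselves stay raw-sample-based, within
    # one fine bin of these)
    base_cmp: dict[str, DoseMetrics] = {}
    for name in names:
        bm = baseline.metrics[name]
        bh = baseline.hists.get(name)
        if bh is not None:
            pdf_b = bh.counts / bh.n
            base_cmp[name] = DoseMetrics(
                D98_Gy=_hist_quantile(pdf_b, bh.edges, 0.02),
                D50_Gy=_hist_quantile(pdf_b, bh.edges, 0.50),
                D2_Gy=_hist_quantile(pdf_b, bh.edges, 0.98),
                Dmean_Gy=bm.Dmean_Gy, V20Gy_pct=bm.V20Gy_pct,
                V50Gy_pct=bm.V50Gy_pct)
        else:
            base_cmp[name] = bm
    deviations = {name: _metric_deviations(metrics[name], base_cmp[name])
                  for name in names}
    flags = {name: {m: (dev is not None
                        and abs(dev) > config.deviation_threshold_pct)
                    for m, dev in devs.items()}
             for name, devs in deviations.items()}
    return AccumulatedResult(metrics=metrics, curves=curves,
                             deviation_pct=deviations, relevant_flags=flags,
                             n_available=len(fraction_results),
                             n_planned=n_planned)


def threshold_exceedance_rate(results, metric: str, structure: str,
                              threshold_pct: float) -> float:
    """Percent of results whose |deviation| for one metric exceeds the
    threshold.  ``results`` may mix :class:`FractionResult` and
    :class:`AccumulatedResult` (both carry ``deviation_pct``)."""
    if metric not in METRIC_NAMES:
        raise LookupError_(f"unknown metric {metric!r}; one of {METRIC_NAMES}")
    count = 0
    total = 0
    for res in results:
        if structure not in res.deviation_pct:
            raise LookupError_(f"structure {structure!r} absent from a result")
        dev = res.deviation_pct[structure][metric]
        if dev is None:
            continue
        total += 1
        if abs(dev) > threshold_pct:
            count += 1
    if total == 0:
        raise LookupError_("no usable deviations")
    return 100.0 * count / total


@dataclass
class CourseReport:
    """Everything the pipeline computed for one course."""

    baseline: Baseline
    fraction_results: list[FractionResult]
    accumulated: AccumulatedResult | None
    failures: list[tuple[int, str]]
    timings_s: dict[str, float]
    config: RunConfig

    def volume_dose_pairs(self, organ: str):
        """(volume deviation %, mean-dose deviation %) per evaluated
        fraction — the pairs entering the volume-dose correlation."""
        vols, doses = [], []
        for fr in self.fraction_results:
            if organ not in fr.geometry:
                raise LookupError_(f"organ {organ!r} absent from report")
            v = fr.geometry[organ].volume_dev_pct
            d = fr.deviation_pct[organ]["Dmean_Gy"]
            if v is None or d is None:
                continue
            vols.append(v)
            doses.append(d)
        return vols, doses

    def volume_series(self, organ: str) -> np.ndarray:
        """Per-fraction absolute volumes (cm^3) of one structure."""
        return np.array([fr.geometry[organ].volume_cm3
                         for fr in self.fraction_results])

    def to_dict(self) -> dict:
        def metrics_d(m):
            return m.as_dict()

        out = {
            "n_fractions_evaluated": len(self.fraction_results),
            "failures": [{"index": i, "error": e} for i, e in self.failures],
            "timings_s": self.timings_s,
            "baseline": {n: metrics_d(m) for n, m in
                         self.baseline.metrics.items()},
            "fractions": [
                {
                    "index": fr.fraction_index,
                    "geometry": {
                        n: {"volume_cm3": g.volume_cm3,
                            "volume_dev_pct": g.volume_dev_pct,
                            "cmd_mm": g.cmd_mm, "dsc": g.dsc,
                            "com_mm": list(g.com)}
                        for n, g in fr.geometry.items()},
                    "metrics": {n: metrics_d(m)
                                for n, m in fr.metrics.items()},
                    "deviation_pct": fr.deviation_pct,
                }
                for fr in self.fraction_results
            ],
        }
        if self.accumulated is not None:
            out["accumulated"] = {
                "n_available": self.accumulated.n_available,
                "n_planned": self.accumulated.n_planned,
                "metrics": {n: metrics_d(m)
                            for n, m in self.accumulated.metrics.items()},
                "deviation_pct": self.accumulated.deviation_pct,
                "relevant_flags": self.accumulated.relevant_flags,
            }
        return out

    def write(self, out_dir, *, plots: bool = False) -> None:
        """Serialize the report: JSON summary plus one CSV per structure
        (one row per fraction) and DVH-curve CSVs; optional overlay plots."""
        import json
        from pathlib import Path

        import pandas as pd

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

        names = list(self.baseline.metrics)
        for name in names:
            rows = []
            for fr in self.fraction_results:
                g = fr.geometry[name]
                row = {"fraction": fr.fraction_index,
                       "volume_cm3": g.volume_cm3,
                       "volume_dev_pct": g.volume_dev_pct,
                       "cmd_mm": g.cmd_mm, "dsc": g.dsc}
                row.update(fr.metrics[name].as_dict())
                row.update({f"dev_{k}_pct": v
                            for k, v in fr.deviation_pct[name].items()})
                rows.append(row)
            safe = name.replace("+", "_plus_")
            pd.DataFrame(rows).to_csv(out_dir / f"fractions_{safe}.csv",
                                      index=False)
            frames = [self.baseline.curves[name].to_frame()
                      .rename(columns={"volume_pct": "baseline"})]
            if self.accumulated is not None:
                frames.append(self.accumulated.curves[name].to_frame()
                              .rename(columns={"volume_pct": "accumulated"}))
            dvh = frames[0]
            for f in frames[1:]:
                dvh = dvh.merge(f, on="dose_gy", how="outer")
            dvh.to_csv(out_dir / f"dvh_{safe}.csv", index=False)

        if plots:
            self._write_plots(out_dir, names)

    def _write_plots(self, out_dir, names) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 5))
        cmap = plt.get_cmap("tab10")
        for i, name in enumerate(names):
            base = self.baseline.curves[name]
            ax.plot(base.dose_axis, base.cum_volume_pct, "--",
                    color=cmap(i % 10), label=f"{name} (plan)")
            if self.accumulated is not None:
                acc = self.accumulated.curves[name]
                ax.plot(acc.dose_axis, acc.cum_volume_pct, "-",
                        color=cmap(i % 10), label=f"{name} (accumulated)")
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel("Volume (%)")
        ax.set_ylim(0, 102)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "dvh_overlay.png", dpi=120)
        plt.close(fig)


def run_course(course: TreatmentCourse,
               config: RunConfig | None = None) -> CourseReport:
    """Run the whole pipeline on one course.

    In lenient mode (default) per-fraction failures are recorded and the
    remaining sessions still enter the accumulation; strict mode re-raises
    the first failure.
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    baseline = evaluate_baseline(course, config)
    timings["baseline"] = time.perf_counter() - t0

    results: list[FractionResult] = []
    failures: list[tuple[int, str]] = []
    t0 = time.perf_counter()
    for frac in course.fractions:
        t_f = time.perf_counter()
        try:
            fr = evaluate_fraction(course, frac, baseline, config)
            results.append(fr)
            log.info("fraction %d evaluated in %.2fs", frac.index,
                     time.perf_counter() - t_f)
        except DoseAccumError as exc:
            if config.strict:
                raise
            log.warning("fraction %d failed: %s", frac.index, exc)
            failures.append((frac.index, str(exc)))
    timings["fractions"] = time.perf_counter() - t0

    accumulated = None
    if results:
        t0 = time.perf_counter()
        accumulated = accumulate(results, baseline,
                                 course.n_fractions_planned, config)
        timings["accumulate"] = time.perf_counter() - t0
    return CourseReport(baseline=baseline, fraction_results=results,
                        accumulated=accumulated, failures=failures,
                        timings_s=timings, config=config)
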