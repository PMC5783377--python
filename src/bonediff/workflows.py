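"""Study-level pipelines built on the detection and quantification layers.

Three analyses are provided, mirroring the way a time-lapse HR-pQCT study
is evaluated in practice:

* ``threshold_sweep`` — repeated (no-change) scan pairs analysed over a
  range of detection thresholds (default 200–275 mg HA/cm**3 in steps of
  25) to choose a threshold whose false-positive level is acceptable;
* ``reproducibility_summary`` — the least-detectable remodelling: the
  apparent formation/resorption between repeated scans, as mean ± SD,
  stratified by motion-artefact quality grade (pairs containing a grade
  >= 3 scan are excluded from the headline figure by default);
* ``longitudinal_analysis`` — each follow-up of a multi-year series
  registered and analysed independently against the same baseline.

Registration is performed once per scan pair and reused across thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .change_detection import (
    FilterParams,
    align_and_subtract,
    cluster_filter,
    threshold_classify,
)
from .core import BinaryMask, DensityVolume, RigidTransform3D, ScanMeta
from .quantification import RemodellingResult, quantify, segment_bvtv

__all__ = [
    "Scan",
    "ScanPair",
    "SweepTable",
    "ReproSummary",
    "DEFAULT_SWEEP_THRESHOLDS",
    "threshold_sweep",
    "reproducibility_summary",
    "longitudinal_analysis",
]

DEFAULT_SWEEP_THRESHOLDS = (200.0, 225.0, 250.0, 275.0)


@dataclass
class Scan:
    """One acquisition: density volume, periosteal mask, metadata and an
    optional trabecular mask used for the BV/TV-matched segmentation."""

    volume: DensityVolume
    mask: BinaryMask
    meta: ScanMeta = field(default_factory=ScanMeta)
    trabecular_mask: BinaryMask | None = None

    @property
    def grade(self) -> int | None:
        return self.meta.quality_grade


@dataclass
class ScanPair:
    """Baseline/follow-up pair of the same subject.

    The pair's quality grade is the worse (max) of the two scans' grades:
    a pair is only as good as its worst image.
    """

    baseline: Scan
    followup: Scan

    def __post_init__(self) -> None:
        if (self.baseline.meta.subject and self.followup.meta.subject
                and self.baseline.meta.subject != self.followup.meta.subject):
            raise ValueError(
                f"pair mixes subjects {self.baseline.meta.subject!r} and "
                f"{self.followup.meta.subject!r}"
            )

    @property
    def grade(self) -> int | None:
        grades = [s.grade for s in (self.baseline, self.followup)
                  if s.grade is not None]
        return max(grades) if grades else None

    @property
    def label(self) -> str:
        return (f"{self.baseline.meta.subject}:"
                f"{self.baseline.meta.timepoint}->{self.followup.meta.timepoint}")


def _segment_baseline(scan: Scan) -> BinaryMask:
    region = scan.trabecular_mask if scan.trabecular_mask is not None else scan.mask
    bone, _ = segment_bvtv(scan.volume, region)
    return bone


def _analyse_pair(
    pair: ScanPair,
    thresholds: list[float],
    params: FilterParams,
    transform: RigidTransform3D | None = None,
) -> dict[float, RemodellingResult]:
    """Register once, then quantify at every threshold."""
    diff, report, lcv, lcv_fraction, _ = align_and_subtract(
        pair.baseline.volume, pair.baseline.mask,
        pair.followup.volume, pair.followup.mask,
        transform=transform,
    )
    bone = _segment_baseline(pair.baseline)
    out: dict[float, RemodellingResult] = {}
    for t in thresholds:
        p = FilterParams(t, params.min_cluster, params.connectivity)
        labels = cluster_filter(threshold_classify(diff, t),
                                p.min_cluster, p.connectivity)
        out[t] = quantify(
            labels, bone, lcv,
            params=p, lcv_fraction=lcv_fraction,
            registration_correlation=report.correlation_after,
        )
    return out


@dataclass
class SweepTable:
    """Per-pair and averaged remodelling fractions per threshold."""

    per_pair: pd.DataFrame  # columns: pair, threshold, formation/resorption/total_pct
    mean: pd.DataFrame      # per threshold, averaged over pairs

    def to_csv(self, path) -> None:
        self.per_pair.to_csv(path, index=False)


def threshold_sweep(
    pairs: list[ScanPair],
    thresholds=DEFAULT_SWEEP_THRESHOLDS,
    params: FilterParams = FilterParams(),
    transforms: list[RigidTransform3D | None] | None = None,
) -> SweepTable:
    """Analyse no-change pairs over a strictly increasing threshold range."""
    if not pairs:
        raise ValueError("need at least one scan pair")
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for i, pair in enumerate(pairs):
        tf = transforms[i] if transforms is not None else None
        for t, res in _analyse_pair(pair, thresholds, params, tf).items():
            rows.append({
                "pair": pair.label or str(i),
                "threshold": t,
                "formation_pct": res.formation_pct,
                "resorption_pct": res.resorption_pct,
                "total_pct": res.formation_pct + res.resorption_pct,
            })
    per_pair = pd.DataFrame(rows).sort_values(["pair", "threshold"],
                                              kind="stable", ignore_index=True)
    mean = (per_pair.drop(columns="pair").groupby("threshold", as_index=False)
            .mean().sort_values("threshold", ignore_index=True))
    return SweepTable(per_pair=per_pair, mean=mean)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else float("nan")
    return mean, sd


@dataclass
class ReproSummary:
    """Least-detectable remodelling: mean ± SD of the apparent formation,
    resorption and net change between repeated scans."""

    all_pairs: dict
    filtered: dict          # pairs with grade <= max_grade (the headline figure)
    per_grade: dict[int, dict]
    max_grade: int
    per_pair: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": "all", **self.all_pairs},
                {"group": f"grade<={self.max_grade}", **self.filtered}]
        rows += [{"group": f"grade={g}", **d}
                 for g, d in sorted(self.per_grade.items())]
        return pd.DataFrame(rows)


def _summarise(results: list[RemodellingResult]) -> dict:
    d = {"n": len(results)}
    for name in ("formation_pct", "resorption_pct", "net_pct"):
        vals = np.array([getattr(r, name) for r in results])
        mean, sd = _mean_sd(vals)
        d[f"{name}_mean"] = mean
        d[f"{name}_sd"] = sd
    return d


def reproducibility_summary(
    pairs: list[ScanPair],
    params: FilterParams = FilterParams(),
    max_grade: int = 2,
    transforms: list[RigidTransform3D | None] | None = None,
) -> ReproSummary:
    """Summarise apparent remodelling over repeated-scan pairs.

    Produces summaries for all pairs, for pairs whose grade is <=
    ``max_grade`` (the reported least-detectable change; low-quality
    images, grade >= 3, are excluded by default) and stratified per grade.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs for a mean ± SD summary")
    results = []
    rows = []
    for i, pair in enumerate(pairs):
        tf = transforms[i] if transforms is not None else None
        res = _analyse_pair(pair, [params.threshold], params, tf)[params.threshold]
        results.append(res)
        rows.append({"pair": pair.label or str(i), "grade": pair.grade,
                     "formation_pct": res.formation_pct,
                     "resorption_pct": res.resorption_pct,
                     "net_pct": res.net_pct})
    grades = [p.grade for p in pairs]
    keep = [r for r, g in zip(results, grades) if g is None or g <= max_grade]
    if not keep:
        raise ValueError(
            f"no pairs with quality grade <= {max_grade}; relax the grade filter"
        )
    per_grade = {}
    for g in sorted({g for g in grades if g is not None}):
        per_grade[g] = _summarise([r for r, gg in zip(results, grades) if gg == g])
    return ReproSummary(
        all_pairs=_summarise(results),
        filtered=_summarise(keep),
        per_grade=per_grade,
        max_grade=max_grade,
        per_pair=pd.DataFrame(rows),
    )


def longitudinal_analysis(
    baseline: Scan,
    followups: list[Scan],
    params: FilterParams = FilterParams(),
    transforms: list[RigidTransform3D | None] | None = None,
) -> dict[str, RemodellingResult]:
    """Analyse an ordered series against a common baseline.

    Each follow-up is registered and analysed independently against the
    same baseline; results are keyed by the follow-up timepoint label.
    Denominators always come from the baseline bone within that pair's
    LCV (per-timepoint LCV, not a common intersection).
    """
    if not followups:
        raise ValueError("need at least one follow-up scan")
    out: dict[str, RemodellingResult] = {}
    for i, fu in enumerate(followups):
        if (baseline.meta.subject and fu.meta.subject
                and fu.meta.subject != baseline.meta.subject):
            raise ValueError("longitudinal series mixes subjects")
        pair = ScanPair(baseline, fu)
        tf = transforms[i] if transforms is not None else None
        key = fu.meta.timepoint or f"followup-{i + 1}"
        out[key] = _analyse_pair(pair, [params.threshold], params, tf)[
            params.threshold]
    return out
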