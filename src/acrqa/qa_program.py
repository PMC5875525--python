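"""Baselines, tolerance derivation and longitudinal evaluation.

The statistical layer of the QA program: initial measurements form a
*baseline*; quarterly results are compared to it; a result is flagged
for investigation when it deviates from baseline by more than the
tolerance.  Tolerances are set at twice the maximum standard deviation
of the metric over all (machine, protocol) groups between baseline
resets — under normality, a result outside 2 SD occurs ~5% of the time
(normality is assumed, not tested).  Bounds are rounded at the
precision the metric is reported at (nearest HU for HU metrics, one
decimal for CNR, two for noise %).  Baselines are reset whenever major
maintenance, recalibration or tube replacement occurs.

Deviations exactly equal to the tolerance pass ("outside" the band
flags).  SDs use the n-1 sample definition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HISTORY_COLUMNS",
    "MeasurementHistory",
    "BaselineRecord",
    "Tolerance",
    "ToleranceSet",
    "establish_baseline",
    "derive_tolerances",
    "derive_tolerances_from_summary",
    "evaluate_session",
    "trend_report",
    "monitor",
    "QAReport",
    "load_reference_summary",
    "load_reference_max_sd",
    "reference_tolerances",
    "round_half_away",
]

HISTORY_COLUMNS = ["machine", "modality", "protocol", "date", "metric", "value", "segment"]


# ---------------------------------------------------------------------------
# measurement history
# ---------------------------------------------------------------------------


class MeasurementHistory:
    """Append-only longitudinal metric records backed by a DataFrame.

    ``segment`` identifies the baseline segment a record belongs to;
    it increments when a baseline is reset (maintenance, recalibration,
    tube replacement).
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=HISTORY_COLUMNS)
        missing = set(HISTORY_COLUMNS) - set(df.columns)
        if missing - {"segment"}:
            raise ValueError(f"history missing columns: {sorted(missing)}")
        if "segment" not in df.columns:
            df = df.assign(segment=0)
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        for (_, _, _, seg), grp in self.df.groupby(
            ["machine", "protocol", "metric", "segment"], sort=False
        ):
            dates = pd.to_datetime(grp["date"])
            if not dates.is_monotonic_increasing:
                raise ValueError(
                    "history dates must be non-decreasing within a baseline segment"
                )

    def append_session(self, session, segment: int = 0) -> None:
        rows = session.history_rows()
        for r in rows:
            r["segment"] = segment
        new = pd.DataFrame(rows)
        self.df = new if self.df.empty else pd.concat([self.df, new], ignore_index=True)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementHistory":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class BaselineRecord:
    machine: str
    protocol: str
    metric: str
    value: float
    segment: int
    date: str
    reason: str = "commissioning"  # | maintenance | recalibration | tube replacement


def establish_baseline(
    history: MeasurementHistory | pd.DataFrame,
    segment: int | None = None,
    k: int = 1,
    reason: str = "commissioning",
) -> dict[tuple[str, str, str], BaselineRecord]:
    """Baselines from the first session(s) of a segment.

    ``k = 1`` (default) uses the first session's values; ``k > 1``
    averages the first k sessions per metric (the preliminary mode used
    when only the first few quarters of data exist).  Returns one
    record per (machine, protocol, metric).
    """
    df = history.df if isinstance(history, MeasurementHistory) else history
    if segment is not None:
        df = df[df["segment"] == segment]
    if df.empty:
        raise ValueError("cannot establish a baseline from an empty history segment")
    out = {}
    for (machine, protocol, metric), grp in df.groupby(
        ["machine", "protocol", "metric"], sort=False
    ):
        grp = grp.sort_values("date", kind="stable")
        head = grp.head(k)
        out[(machine, protocol, metric)] = BaselineRecord(
            machine=machine,
            protocol=protocol,
            metric=metric,
            value=float(head["value"].mean()),
            segment=int(grp["segment"].iloc[0]),
            date=str(head["date"].iloc[-1]),
            reason=reason,
        )
    return out


# ---------------------------------------------------------------------------
# tolerance derivation
# ---------------------------------------------------------------------------


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (2 x 7.9 = 15.8 -> 16; 0.5 -> 1)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


_ROUNDING_DECIMALS = {
    "hu": 0,
    "uniformity": 1,
    "cnr": 1,
    "low_contrast_cnr": 1,
    "noise": 2,
    "distance": 1,
    "slice_thickness": 1,
    "high_contrast": 0,
}


def rounding_decimals(metric: str) -> int:
    """Reporting precision of a metric id (drives tolerance rounding)."""
    for prefix, dec in _ROUNDING_DECIMALS.items():
        if metric == prefix or metric.startswith(prefix + "_") or metric.startswith(prefix):
            return dec
    return 2


@dataclass
class Tolerance:
    metric: str
    bound: float
    mode: str = "delta"  # delta-from-baseline | absolute | minimum
    # center of the band in absolute mode; None means "the nominal value
    # supplied at evaluation time" (e.g. the protocol's slice thickness)
    reference: float | None = 0.0
    units: str = ""
    provenance: str = "derived-2xmaxSD"  # | fixed-ACR | worst-case | config
    rounding_decimals: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mode == "delta" and self.bound < 0:
            raise ValueError("delta tolerance bound must be >= 0")


class ToleranceSet(dict):
    """Mapping metric id -> :class:`Tolerance` with YAML persistence."""

    def add(self, tol: Tolerance) -> "ToleranceSet":
        self[tol.metric] = tol
        return self

    def to_yaml(self, path=None) -> str:
        payload = {m: asdict(t) for m, t in sorted(self.items())}
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ToleranceSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        out = cls()
        for metric, d in payload.items():
            d = dict(d)
            d["metric"] = metric
            out.add(Tolerance(**d))
        return out


def _derive_from_group_sds(
    sds: pd.Series, metric: str, provenance: str
) -> Tolerance:
    max_sd = float(sds.max())
    dec = rounding_decimals(metric)
    bound = round_half_away(2.0 * max_sd, dec)
    return Tolerance(
        metric=metric,
        bound=bound,
        mode="delta",
        provenance=provenance,
        rounding_decimals=dec,
        degenerate=bool(max_sd == 0.0),
    )


def derive_tolerances(
    history: MeasurementHistory | pd.DataFrame,
    grouping: Sequence[str] = ("machine", "protocol"),
    min_records: int = 2,
) -> ToleranceSet:
    """2 x max-SD tolerances from raw longitudinal records.

    The SD is computed within each grouping-key group between baseline
    resets (the ``segment`` column); the tolerance for a metric is
    twice the maximum group SD, rounded at the metric's reporting
    precision.  Groups with fewer than ``min_records`` values (SD
    undefined) are skipped; metrics with no usable group are omitted.
    An all-identical history yields tolerance 0 flagged degenerate.
    """
    df = history.df if isinstance(history, MeasurementHistory) else history
    keys = list(grouping) + (["segment"] if "segment" in df.columns else [])
    out = ToleranceSet()
    for metric, mgrp in df.groupby("metric", sort=False):
        sds = (
            mgrp.groupby(keys, sort=False)["value"]
            .agg(["count", lambda v: v.std(ddof=1)])
            .rename(columns={"<lambda_0>": "sd"})
        )
        sds = sds[sds["count"] >= min_records]["sd"].dropna()
        if sds.empty:
            continue
        out.add(_derive_from_group_sds(sds, metric, "derived-2xmaxSD"))
    return out


def derive_tolerances_from_summary(
    summary: pd.DataFrame, provenance: str = "derived-2xmaxSD"
) -> ToleranceSet:
    """2 x max-SD tolerances from already-summarized groups.

    ``summary`` needs columns ``metric`` and ``sd`` (one row per
    machine/protocol group); any other columns are carried grouping
    labels and ignored.  This is the entry point for tolerance
    derivation from published per-protocol mean/SD tables.
    """
    if not {"metric", "sd"} <= set(summary.columns):
        raise ValueError("summary requires 'metric' and 'sd' columns")
    out = ToleranceSet()
    for metric, grp in summary.groupby("metric", sort=False):
        out.add(_derive_from_group_sds(grp["sd"].astype(float), metric, provenance))
    return out


# ---------------------------------------------------------------------------
# reference data (two-year CT/CBCT QA program) and default tolerance sets
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("acrqa.data").joinpath(name)


def load_reference_summary(modality: str | None = None) -> pd.DataFrame:
    """Per-protocol CNR / noise mean and SD from the reference two-year
    quarterly QA program (one fan-beam CT simulator, three linac CBCTs)."""
    df = pd.read_csv(_data_path("reference_cnr_noise_summary.csv"))
    if modality is not None:
        df = df[df["modality"] == modality].reset_index(drop=True)
    return df

def load_reference_max_sd(modality: str | None = None) -> pd.DataFrame:
    """Maximum between-baseline SDs of the HU / uniformity / distance
    metrics from the same reference program (reported as maxima only)."""
    df = pd.read_csv(_data_path("reference_max_sd.csv"))
    if modality is not None:
        df = df[df["modality"] == modality].reset_index(drop=True)
    return df


def reference_tolerances(modality: str) -> ToleranceSet:
    """Tolerance set derived at call time from the reference program data.

    CNR and noise bounds come from the per-protocol SD tables; HU,
    uniformity and distance bounds from the published maximum SDs; the
    remaining bounds are the fixed recommendations (slice thickness
    ±0.5 mm of nominal, high contrast ±1 lp/cm of baseline, in-plane
    distance ±1.0 mm of the nominal 100.0 mm).  The CBCT bone plug is
    deliberately absent: its observed SD (29.1 HU) is inconsistent with
    any published bound, so a bone tolerance must be configured
    explicitly.
    """
    modality = modality.upper()
    if modality not in ("CT", "CBCT"):
        raise ValueError("modality must be CT or CBCT")
    tols = derive_tolerances_from_summary(load_reference_summary(modality))
    max_sd = load_reference_max_sd(modality)
    for _, row in max_sd.iterrows():
        metric = row["metric"]
        if metric == "hu_bone":
            continue  # see docstring
        dec = rounding_decimals(metric)
        tols.add(
            Tolerance(
                metric=metric,
                bound=round_half_away(2.0 * float(row["max_sd"]), dec),
                mode="delta",
                provenance="derived-2xmaxSD",
                rounding_decimals=dec,
            )
        )
    if modality == "CT":
        # stated recommendation (about twice the 1.1 HU max plug SD)
        for plug in ("air", "polyethylene", "water", "acrylic", "bone"):
            tols.add(
                Tolerance(
                    metric=f"hu_{plug}", bound=3.0, mode="delta", units="HU",
                    provenance="fixed-recommendation",
                )
            )
        tols.add(
            Tolerance(
                metric="low_contrast_cnr_min", bound=1.0, mode="minimum",
                provenance="fixed-ACR",
                rounding_decimals=1,
            )
        )
    tols.add(
        Tolerance(
            metric="distance_mm", bound=1.0, mode="absolute", reference=100.0,
            units="mm", provenance="worst-case", rounding_decimals=1,
        )
    )
    tols.add(
        Tolerance(
            metric="slice_thickness_mm", bound=0.5, mode="absolute",
            reference=None, units="mm", provenance="worst-case",
            rounding_decimals=1,
        )
    )
    tols.add(
        Tolerance(
            metric="high_contrast_lp_cm", bound=1.0, mode="delta",
            units="lp/cm", provenance="worst-case", rounding_decimals=0,
        )
    )
    return tols


# ---------------------------------------------------------------------------
# session evaluation
# ---------------------------------------------------------------------------


@dataclass
class ReportRow:
    metric: str
    value: float | None
    baseline: float | None
    deviation: float | None
    tolerance: float | None
    mode: str
    status: str  # pass | action | not-evaluable
    reason: str = ""


@dataclass
class QAReport:
    machine: str
    protocol: str
    date: str
    rows: list[ReportRow] = field(default_factory=list)

    @property
    def any_action(self) -> bool:
        return any(r.status == "action" for r in self.rows)

    def actions(self) -> list[ReportRow]:
        return [r for r in self.rows if r.status == "action"]

    def to_json(self, path=None) -> str:
        payload = {
            "machine": self.machine,
            "protocol": self.protocol,
            "date": self.date,
            "any_action": self.any_action,
            "rows": [asdict(r) for r in self.rows],
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"QA report  machine={self.machine}  protocol={self.protocol}  "
            f"date={self.date}",
            f"{'metric':<28}{'value':>10}{'baseline':>10}{'dev':>8}"
            f"{'tol':>8}  status",
        ]
        for r in self.rows:
            fmt = lambda v: "-" if v is None else f"{v:.2f}"
            lines.append(
                f"{r.metric:<28}{fmt(r.value):>10}{fmt(r.baseline):>10}"
                f"{fmt(r.deviation):>8}{fmt(r.tolerance):>8}  {r.status}"
                + (f" ({r.reason})" if r.reason else "")
            )
        return "\n".join(lines)


def evaluate_session(
    session,
    baselines: dict,
    tolerances: ToleranceSet,
    nominal_slice_thickness: float | None = None,
) -> QAReport:
    """Compare one session's metrics to baselines under the tolerances.

    ``session`` is a :class:`acrqa.metrics.QASession` or a plain dict of
    metric values plus machine/protocol/date attributes access via keys.
    A deviation exactly equal to the bound passes.  Idempotent and
    side-effect free.
    """
    if hasattr(session, "metric_values"):
        values = session.metric_values()
        machine, protocol, date = session.machine, session.protocol, session.date
        not_evaluable = dict(getattr(session, "not_evaluable", {}))
    else:
        values = dict(session)
        machine = values.pop("machine", "")
        protocol = values.pop("protocol", "")
        date = values.pop("date", "")
        not_evaluable = {}

    def baseline_for(metric: str) -> float | None:
        if (machine, protocol, metric) in baselines:
            return baselines[(machine, protocol, metric)].value
        rec = baselines.get(metric)
        if rec is None:
            return None
        return rec.value if hasattr(rec, "value") else float(rec)

    report = QAReport(machine=machine, protocol=protocol, date=date)
    for metric, tol in sorted(tolerances.items()):
        target = metric[: -len("_min")] if metric.endswith("_min") else metric
        value = values.get(target)
        if value is None:
            reason = not_evaluable.get(target, not_evaluable.get(
                target.split("_")[0], "metric missing from session"
            ))
            report.rows.append(
                ReportRow(metric, None, None, None, tol.bound, tol.mode,
                          "not-evaluable", reason)
            )
            continue
        if tol.mode == "delta":
            base = baseline_for(target)
            if base is None:
                report.rows.append(
                    ReportRow(metric, value, None, None, tol.bound, tol.mode,
                              "not-evaluable", "no baseline")
                )
                continue
            dev = value - base
            status = "pass" if abs(dev) <= tol.bound else "action"
            report.rows.append(
                ReportRow(metric, value, base, dev, tol.bound, tol.mode, status)
            )
        elif tol.mode == "absolute":
            ref = tol.reference
            if ref is None:
                if nominal_slice_thickness is None:
                    report.rows.append(
                        ReportRow(metric, value, None, None, tol.bound, tol.mode,
                                  "not-evaluable", "no nominal value supplied")
                    )
                    continue
                ref = nominal_slice_thickness
            dev = value - ref
            status = "pass" if abs(dev) <= tol.bound else "action"
            report.rows.append(
                ReportRow(metric, value, ref, dev, tol.bound, tol.mode, status)
            )
        elif tol.mode == "minimum":
            status = "pass" if value >= tol.bound else "action"
            report.rows.append(
                ReportRow(metric, value, None, None, tol.bound, tol.mode, status)
            )
        else:
            raise ValueError(f"unknown tolerance mode {tol.mode!r}")
    return report


# ---------------------------------------------------------------------------
# trending and longitudinal monitoring
# ---------------------------------------------------------------------------


def trend_report(history: MeasurementHistory | pd.DataFrame) -> pd.DataFrame:
    """Per (machine, protocol, metric, segment): n, mean, SD, date range.

    Metrics with no records are simply absent.  The result is the
    tabular companion of the trend plots (per-segment mean ± 1 SD with
    baseline-reset boundaries).
    """
    df = history.df if isinstance(history, MeasurementHistory) else history
    if df.empty:
        raise ValueError("empty history")
    agg = (
        df.groupby(["machine", "protocol", "metric", "segment"], sort=False)
        .agg(
            n=("value", "size"),
            mean=("value", "mean"),
            sd=("value", lambda v: v.std(ddof=1)),
            first_date=("date", "min"),
            last_date=("date", "max"),
        )
        .reset_index()
    )
    return agg


def monitor(
    session_values: Iterable[dict],
    tolerances: ToleranceSet,
    baseline_k: int = 1,
    reset_on_action: bool = True,
    nominal_slice_thickness: float | None = None,
) -> tuple[list[QAReport], list[int], list[int]]:
    """Sequentially evaluate sessions, re-baselining after actions.

    Each element of ``session_values`` is a dict of metric values (may
    include machine/protocol/date keys).  The first session of each
    segment establishes the baseline (mean of the first ``baseline_k``
    sessions once available; until then, of those seen).  When a
    delta-mode action fires and ``reset_on_action`` is set, the next
    session starts a new baseline segment — the investigate/recalibrate
    /re-baseline loop of a clinical program.

    Returns (reports, segment id per session, sessions where a reset
    occurred).
    """
    reports: list[QAReport] = []
    segments: list[int] = []
    resets: list[int] = []
    segment = 0
    seg_values: list[dict] = []

    def build_baseline() -> dict:
        base: dict = {}
        take = seg_values[:baseline_k]
        keys = set().union(*(set(v) for v in take))
        for key in keys:
            vals = [v[key] for v in take if key in v and isinstance(v[key], (int, float))]
            if vals:
                base[key] = float(np.mean(vals))
        return base

    for i, values in enumerate(session_values):
        clean = {
            k: v for k, v in values.items() if isinstance(v, (int, float))
        }
        if not seg_values:
            seg_values.append(clean)
        else:
            seg_values.append(clean)
        baseline = build_baseline()
        report = evaluate_session(
            dict(values), baseline, tolerances, nominal_slice_thickness
        )
        reports.append(report)
        segments.append(segment)
        if reset_on_action and report.any_action:
            segment += 1
            seg_values = []
            resets.append(i)
    return reports, segments, resets
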