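"""Per-tooth pipeline orchestration and cohort summaries.

``run_tooth`` chains the whole measurement: read meshes → prealign →
trimmed ICP → transform into the reference frame → signed deviation field →
labeling → per-side statistics, volumes, histograms, connected regions and
(optionally) ARI scores.  ``cohort_summary`` aggregates a set of per-tooth
reports into the study-level numbers (median/mean/extreme volumes and
heights), and ``summarize_table`` computes the same aggregate directly from
a printed per-tooth statistics table, which is how published results are
reproduced when the underlying scans are not available.

Two per-tooth statistics tables from the original debonding experiment
(15 extracted human third molars; adhesive remnants and enamel loss) ship
with the package as ``data/table1.csv`` and ``data/table2.csv``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .deviation import DeviationField, signed_deviation
from .mesh_io import TriangleSurface, read_mesh
from .quantify import (
    LOSS,
    REMNANT,
    ARIScores,
    ChangeRegion,
    Histogram,
    SideStatistics,
    compute_ari,
    connected_regions,
    deviation_histogram,
    dilate_vertex_mask,
    label_field,
    side_statistics,
)
from .registration import (
    RegistrationResult,
    apply_transform,
    icp_register,
    prealign,
)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "ToothChangeReport",
    "TableSummary",
    "CohortSummary",
    "run_tooth",
    "run_tooth_surfaces",
    "cohort_summary",
    "summarize_table",
    "read_table",
    "load_bundled_table",
    "render_report",
    "round_half_away",
]

_TABLE_COLUMNS = ("mean", "sd", "max", "min", "volume")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.error = error
        super().__init__(f"stage {stage!r}: {error}")


@dataclass
class PipelineConfig:
    """Resolved parameters of one per-tooth run.

    All lengths in mm.  ``sd_convention`` selects sample (n−1) or
    population (n) SD for the table statistics; ``noise_floor`` defaults to
    the scanner precision (2 μm).  ``footprint_polygon``, when given, is
    used both as an ICP exclusion region and as the ARI base area;
    otherwise ``base_area`` (mm², e.g. the nominal tube base) enables ARI.
    """

    trim_fraction: float = 0.3
    tol: float = 1e-6
    max_iter: int = 100
    refine_registration: bool = True
    refine_trim: float = 0.05
    refine_max_points: int | None = 12000
    icp_max_points: int | None = 5000
    max_distance: float = 2.0
    noise_floor: float = 0.002
    hard_threshold: bool = False
    bin_width: float = 0.02
    sd_convention: str = "sample"  # or "population"
    min_region_area: float = 0.2
    base_area: float | None = None
    footprint_polygon: list[tuple[float, float]] | None = None

    @property
    def sd_ddof(self) -> int:
        if self.sd_convention not in ("sample", "population"):
            raise ValueError("sd_convention must be 'sample' or 'population'")
        return 1 if self.sd_convention == "sample" else 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["footprint_polygon"] is not None:
            d["footprint_polygon"] = [list(p) for p in d["footprint_polygon"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        poly = d.get("footprint_polygon")
        if poly is not None:
            d["footprint_polygon"] = [tuple(p) for p in poly]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# report containers

@dataclass
class ToothChangeReport:
    """Everything measured for one tooth.

    ``remnant``/``loss`` are the table-parity statistics (soft labeling:
    every signed deviation counts, sub-precision values flagged upstream).
    The ``*_region_*`` fields come from hard-threshold labeling plus
    connected-region extraction with a minimum-area filter — the denoised
    totals used for parameter recovery and for counting distinct remnants.
    """

    tooth_id: str
    remnant: SideStatistics
    loss: SideStatistics
    remnant_histogram: Histogram | None
    loss_histogram: Histogram | None
    n_remnant_regions: int
    n_loss_regions: int
    remnant_region_volume: float
    loss_region_volume: float
    remnant_region_area: float
    loss_region_area: float
    remnant_max_amplitude: float | None
    loss_max_amplitude: float | None
    ari: ARIScores | None
    registration: dict
    config: dict

    def to_dict(self) -> dict:
        def hist(h):
            if h is None:
                return None
            return {"bin_edges": h.bin_edges.tolist(), "percent": h.percent.tolist()}

        d = {
            "tooth_id": self.tooth_id,
            "remnant": asdict(self.remnant),
            "loss": asdict(self.loss),
            "remnant_histogram": hist(self.remnant_histogram),
            "loss_histogram": hist(self.loss_histogram),
            "n_remnant_regions": self.n_remnant_regions,
            "n_loss_regions": self.n_loss_regions,
            "remnant_region_volume": self.remnant_region_volume,
            "loss_region_volume": self.loss_region_volume,
            "remnant_region_area": self.remnant_region_area,
            "loss_region_area": self.loss_region_area,
            "remnant_max_amplitude": self.remnant_max_amplitude,
            "loss_max_amplitude": self.loss_max_amplitude,
            "ari": None if self.ari is None else asdict(self.ari),
            "registration": self.registration,
            "config": self.config,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToothChangeReport":
        def hist(h):
            if h is None:
                return None
            return Histogram(np.asarray(h["bin_edges"]), np.asarray(h["percent"]))

        return cls(
            tooth_id=d["tooth_id"],
            remnant=SideStatistics(**d["remnant"]),
            loss=SideStatistics(**d["loss"]),
            remnant_histogram=hist(d["remnant_histogram"]),
            loss_histogram=hist(d["loss_histogram"]),
            n_remnant_regions=d["n_remnant_regions"],
            n_loss_regions=d["n_loss_regions"],
            remnant_region_volume=d["remnant_region_volume"],
            loss_region_volume=d["loss_region_volume"],
            remnant_region_area=d["remnant_region_area"],
            loss_region_area=d["loss_region_area"],
            remnant_max_amplitude=d["remnant_max_amplitude"],
            loss_max_amplitude=d["loss_max_amplitude"],
            ari=None if d["ari"] is None else ARIScores(**d["ari"]),
            registration=d["registration"],
            config=d["config"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ToothChangeReport":
        return cls.from_dict(json.loads(text))


@dataclass
class TableSummary:
    """Cohort aggregate of one side's per-tooth table.

    ``mean_min``/``mean_max`` span the per-tooth Mean column (empty-side
    teeth excluded), ``global_max`` is the largest single height/depth, and
    the volume statistics include empty-side teeth at volume 0.
    """

    n_teeth: int
    volume_median: float
    volume_mean: float
    volume_min: float
    volume_max: float
    mean_min: float | None
    mean_max: float | None
    global_max: float | None

    def __post_init__(self):
        if not self.volume_min <= self.volume_median <= self.volume_max:
            raise ValueError("volume summaries violate min <= median <= max")
        if not self.volume_min <= self.volume_mean <= self.volume_max:
            raise ValueError("volume summaries violate min <= mean <= max")


@dataclass
class CohortSummary:
    """Study-level summary over all teeth, per side."""

    remnant: TableSummary
    loss: TableSummary
    n_teeth: int


# ---------------------------------------------------------------------------
# the per-tooth pipeline

def run_tooth(
    pre_path: str | Path,
    post_path: str | Path,
    config: PipelineConfig | None = None,
    tooth_id: str | None = None,
) -> ToothChangeReport:
    """Run the full measurement for one tooth from a pre/post mesh pair."""
    config = config or PipelineConfig()
    try:
        pre = read_mesh(pre_path)
        post = read_mesh(post_path)
    except Exception as exc:
        raise PipelineStageError("read_mesh", exc) from exc
    if tooth_id is None:
        tooth_id = Path(post_path).stem
    return run_tooth_surfaces(pre, post, config, tooth_id)


def run_tooth_surfaces(
    pre: TriangleSurface,
    post: TriangleSurface,
    config: PipelineConfig | None = None,
    tooth_id: str = "tooth",
) -> ToothChangeReport:
    """Same as :func:`run_tooth` on in-memory surfaces (phantoms, tests)."""
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    init = stage("prealign", prealign, post, pre)

    mask = None
    if config.footprint_polygon is not None:
        moved = init.apply(post.vertices)[:, :2]
        mask = _points_in_polygon(moved, np.asarray(config.footprint_polygon))

    reg: RegistrationResult = stage(
        "icp_register",
        icp_register,
        post,
        pre,
        trim_fraction=config.trim_fraction,
        tol=config.tol,
        max_iter=config.max_iter,
        init=init,
        max_points=config.icp_max_points,
        exclusion_mask=mask,
    )
    if config.refine_registration:
        # second pass: exclude the vertices the first pass flagged as changed
        # (dilated to catch sub-floor feature periphery) and re-fit with
        # minimal trimming, so the changed region cannot bias the pose at all
        registered0 = stage("apply_transform", apply_transform, post, reg.transform)
        fld0 = stage(
            "signed_deviation", signed_deviation, registered0, pre, config.max_distance
        )
        with np.errstate(invalid="ignore"):
            changed = fld0.valid & (np.abs(fld0.deviation) > config.noise_floor)
        exclude = dilate_vertex_mask(changed, post.faces, rings=3) | ~fld0.valid
        if mask is not None:
            exclude |= mask
        if (~exclude).sum() >= 100:
            reg = stage(
                "icp_register",
                icp_register,
                post,
                pre,
                trim_fraction=config.refine_trim,
                tol=config.tol,
                max_iter=config.max_iter,
                init=reg.transform,
                max_points=config.refine_max_points,
                exclusion_mask=exclude,
            )

    registered = stage("apply_transform", apply_transform, post, reg.transform)
    fld: DeviationField = stage(
        "signed_deviation", signed_deviation, registered, pre, config.max_distance
    )
    soft = stage(
        "label_field", label_field, fld, config.noise_floor, config.hard_threshold
    )
    hard = stage("label_field", label_field, fld, config.noise_floor, True)

    rem = stage("side_statistics", side_statistics, fld, soft, REMNANT, config.sd_ddof)
    los = stage("side_statistics", side_statistics, fld, soft, LOSS, config.sd_ddof)
    rem_hist = (
        None
        if rem.is_empty
        else stage("deviation_histogram", deviation_histogram, fld, soft, REMNANT, config.bin_width)
    )
    los_hist = (
        None
        if los.is_empty
        else stage("deviation_histogram", deviation_histogram, fld, soft, LOSS, config.bin_width)
    )

    regions: list[ChangeRegion] = stage(
        "connected_regions", connected_regions, fld, hard, config.min_region_area
    )
    rregs = [r for r in regions if r.side == REMNANT]
    lregs = [r for r in regions if r.side == LOSS]

    ari = None
    base_area = config.base_area
    if base_area is None and config.footprint_polygon is not None:
        base_area = _polygon_area(np.asarray(config.footprint_polygon))
    if base_area is not None:
        ari = stage(
            "compute_ari", compute_ari, sum(r.area for r in rregs), base_area
        )

    return ToothChangeReport(
        tooth_id=tooth_id,
        remnant=rem,
        loss=los,
        remnant_histogram=rem_hist,
        loss_histogram=los_hist,
        n_remnant_regions=len(rregs),
        n_loss_regions=len(lregs),
        remnant_region_volume=sum(r.volume for r in rregs),
        loss_region_volume=sum(r.volume for r in lregs),
        remnant_region_area=sum(r.area for r in rregs),
        loss_region_area=sum(r.area for r in lregs),
        remnant_max_amplitude=max((r.max_amplitude for r in rregs), default=None),
        loss_max_amplitude=max((r.max_amplitude for r in lregs), default=None),
        ari=ari,
        registration={
            "matrix": reg.transform.to_matrix().tolist(),
            "rms_residual": reg.rms_residual,
            "retained_fraction": reg.retained_fraction,
            "iterations": reg.iterations,
            "converged": reg.converged,
        },
        config=config.to_dict(),
    )


def _points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorized over points."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


def _polygon_area(polygon: np.ndarray) -> float:
    x, y = polygon[:, 0], polygon[:, 1]
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


# ---------------------------------------------------------------------------
# cohort aggregation

def cohort_summary(reports: list[ToothChangeReport]) -> CohortSummary:
    """Aggregate per-tooth reports into study-level numbers.

    Teeth with an empty side contribute volume 0 to that side's volume
    statistics but are excluded from the per-tooth mean-height range and
    the global maximum.  The median for even n is the mean of the two
    central order statistics.
    """
    if not reports:
        raise ValueError("cohort_summary needs at least one report")
    sides = {}
    for side in (REMNANT, LOSS):
        stats = [getattr(r, side) for r in reports]
        volumes = np.array([0.0 if s.is_empty else s.volume for s in stats])
        means = [s.mean for s in stats if not s.is_empty]
        maxes = [s.max for s in stats if not s.is_empty]
        sides[side] = TableSummary(
            n_teeth=len(reports),
            volume_median=float(np.median(volumes)),
            volume_mean=float(volumes.mean()),
            volume_min=float(volumes.min()),
            volume_max=float(volumes.max()),
            mean_min=min(means) if means else None,
            mean_max=max(means) if means else None,
            global_max=max(maxes) if maxes else None,
        )
    return CohortSummary(remnant=sides[REMNANT], loss=sides[LOSS], n_teeth=len(reports))


def summarize_table(rows) -> TableSummary:
    """Cohort summary straight from a printed per-tooth statistics table.

    ``rows`` is a DataFrame (or anything convertible) with numeric columns
    Mean, SD, Max, Min, Volume (case-insensitive), one row per tooth.
    """
    df = pd.DataFrame(rows)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    for i, row in df.iterrows():
        for c in _TABLE_COLUMNS:
            value = row[c]
            if not isinstance(value, (int, float, np.floating, np.integer)) or (
                isinstance(value, float) and math.isnan(value)
            ):
                raise ValueError(f"row {i}: column {c!r} is not numeric ({value!r})")
    volumes = df["volume"].to_numpy(dtype=float)
    return TableSummary(
        n_teeth=len(df),
        volume_median=float(np.median(volumes)),
        volume_mean=float(volumes.mean()),
        volume_min=float(volumes.min()),
        volume_max=float(volumes.max()),
        mean_min=float(df["mean"].min()),
        mean_max=float(df["mean"].max()),
        global_max=float(df["max"].max()),
    )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a per-tooth statistics table (CSV with Mean/SD/Max/Min/Volume)."""
    return pd.read_csv(path)


def load_bundled_table(which: str) -> pd.DataFrame:
    """The shipped per-tooth reference tables.

    ``which`` is ``"remnants"`` (adhesive-remnant heights and volumes,
    data/table1.csv) or ``"loss"`` (enamel-loss depths and volumes,
    data/table2.csv), both from the 15-molar debonding experiment.
    """
    names = {"remnants": "table1.csv", "loss": "table2.csv"}
    if which not in names:
        raise ValueError("which must be 'remnants' or 'loss'")
    ref = resources.files("debondmetry").joinpath("data", names[which])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


# ---------------------------------------------------------------------------
# rendering

def render_report(obj, format: str = "json") -> str:
    """Serialize a ToothChangeReport or CohortSummary as csv/json/markdown."""
    if format == "json":
        if isinstance(obj, ToothChangeReport):
            return obj.to_json()
        if isinstance(obj, CohortSummary):
            return json.dumps(
                {
                    "n_teeth": obj.n_teeth,
                    "remnant": asdict(obj.remnant),
                    "loss": asdict(obj.loss),
                },
                indent=2,
            )
        if isinstance(obj, TableSummary):
            return json.dumps(asdict(obj), indent=2)
    elif format == "csv":
        return _render_csv(obj)
    elif format == "markdown":
        return _render_markdown(obj)
    else:
        raise ValueError(f"unknown format {format!r}; expected csv, json or markdown")
    raise ValueError(f"cannot render {type(obj).__name__} as {format}")


def _fmt_value(v) -> str:
    return "" if v is None else repr(float(v))


def _render_csv(obj) -> str:
    if isinstance(obj, ToothChangeReport):
        lines = ["tooth,side,Mean,SD,Max,Min,Volume"]
        for side_name, s in (("remnant", obj.remnant), ("loss", obj.loss)):
            lines.append(
                ",".join(
                    [obj.tooth_id, side_name]
                    + [_fmt_value(v) for v in (s.mean, s.sd, s.max, s.min, s.volume)]
                )
            )
        return "\n".join(lines) + "\n"
    if isinstance(obj, (CohortSummary, TableSummary)):
        pairs = _summary_pairs(obj)
        header = ",".join(k for k, _ in pairs)
        values = ",".join(_fmt_value(v) if isinstance(v, float) else str(v) for _, v in pairs)
        return header + "\n" + values + "\n"
    raise ValueError(f"cannot render {type(obj).__name__} as csv")


def _summary_pairs(obj):
    if isinstance(obj, TableSummary):
        return list(asdict(obj).items())
    pairs = [("n_teeth", obj.n_teeth)]
    for side_name in ("remnant", "loss"):
        for k, v in asdict(getattr(obj, side_name)).items():
            if k != "n_teeth":
                pairs.append((f"{side_name}_{k}", v))
    return pairs


def _render_markdown(obj) -> str:
    if isinstance(obj, ToothChangeReport):
        lines = [
            f"# Tooth {obj.tooth_id}",
            "",
            "| side | Mean | SD | Max | Min | Volume |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        for side_name, s in (("remnant", obj.remnant), ("loss", obj.loss)):
            if s.is_empty:
                lines.append(f"| {side_name} | – | – | – | – | – |")
            else:
                lines.append(
                    f"| {side_name} | {s.mean:.4g} | {s.sd:.4g} | {s.max:.4g} "
                    f"| {s.min:.4g} | {s.volume:.4g} |"
                )
        lines.append("")
        lines.append(
            f"regions: {obj.n_remnant_regions} remnant "
            f"({obj.remnant_region_volume:.4g} mm³), "
            f"{obj.n_loss_regions} loss ({obj.loss_region_volume:.4g} mm³)"
        )
        if obj.ari is not None:
            lines.append(
                f"ARI: Årtun–Bergland {obj.ari.artun_bergland}, "
                f"Krell {obj.ari.krell}, Osorio {obj.ari.osorio_percent:.1f}%"
            )
        return "\n".join(lines) + "\n"
    if isinstance(obj, (CohortSummary, TableSummary)):
        n = obj.n_teeth
        lines = [f"# Cohort summary (n_teeth = {n})", "", "| quantity | value |", "| --- | --- |"]
        for k, v in _summary_pairs(obj):
            if k == "n_teeth":
                continue
            lines.append(f"| {k} | {'' if v is None else format(v, '.4g')} |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"cannot render {type(obj).__name__} as markdown")


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero — the convention printed tables use."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
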