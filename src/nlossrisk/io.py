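"""Scenario I/O: CSV schemas, validated loading, and report writing.

A scenario directory holds plain CSV tables (RFC-4180, UTF-8, "." decimal):

======================  ========================================================
blocks.csv              block_id, area_ha, land_use, soil_id, slope, climate_id,
                        irrigated[, lon, lat]
soils.csv               soil_id, layer_index, thickness_mm, theta_sat, theta_fc,
                        theta_wp, drainage_coefficient, runoff_curve_parameter,
                        total_n_fraction, bulk_density
climate.csv             climate_id, date, rain_mm, pet_mm
stock.csv               block_id, month, stock_class, age_class, region, head
fertilizer.csv          block_id, month, product_id, mass_kg_ha
products.csv            product_id, n_fraction
excreta_rates.csv       stock_class, age_class, region, urine_n_kg_head_month,
                        dung_n_kg_head_month
crops.csv               block_id, crop_id, yield_t_ha, harvest_month,
                        residue_fraction_ag, n_conc_ag_kg_t, n_conc_bg_kg_t,
                        cn_ratio, rooting_class
cultivation.csv         block_id, pasture_age_class, enterprise, start_month,
                        fallow_months
erosion.csv             block_id, land_use, slope, season, cover_factor,
                        land_use_multiplier, soil_total_n_fraction
observations.csv        obs_id, land_use, flow_path, loss_kg_ha_yr, measured,
                        n_form, low_confidence, location
config.yaml             effluent_n_kg_per_cow_month, seed, ...
======================  ========================================================

Only ``blocks.csv``, ``soils.csv`` and ``climate.csv`` are required; the
management tables default to empty (an empty management file is a valid
scenario with all-zero sources).  Loading collects all schema and
foreign-key problems and reports them together, naming file and field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .index_engine import Block, RiskScore, aggregate_risk
from .mitigation import ModifierStep
from .sources import (
    BlockCalendar,
    CropRecord,
    CultivationEvent,
    ErosionContext,
    ExcretaRateTable,
    FertilizerApplication,
)
from .synthetic import FixtureFarm
from .transport import ClimateSeries, SoilLayer, SoilProfile
from .validation import ObservationRecord, RankRegressionResult

__all__ = [
    "ScenarioError",
    "load_scenario",
    "write_scenario",
    "load_observations",
    "write_risk_report",
    "write_rank_plot",
]

MILKING_KEY = ("dairy_cattle", "milking")

REQUIRED_COLUMNS = {
    "blocks.csv": ["block_id", "area_ha", "land_use", "soil_id", "slope", "climate_id", "irrigated"],
    "soils.csv": [
        "soil_id", "layer_index", "thickness_mm", "theta_sat", "theta_fc", "theta_wp",
        "drainage_coefficient", "runoff_curve_parameter", "total_n_fraction", "bulk_density",
    ],
    "climate.csv": ["climate_id", "date", "rain_mm", "pet_mm"],
    "stock.csv": ["block_id", "month", "stock_class", "age_class", "region", "head"],
    "fertilizer.csv": ["block_id", "month", "product_id", "mass_kg_ha"],
    "products.csv": ["product_id", "n_fraction"],
    "excreta_rates.csv": [
        "stock_class", "age_class", "region", "urine_n_kg_head_month", "dung_n_kg_head_month",
    ],
    "crops.csv": [
        "block_id", "crop_id", "yield_t_ha", "harvest_month", "residue_fraction_ag",
        "n_conc_ag_kg_t", "n_conc_bg_kg_t", "cn_ratio", "rooting_class",
    ],
    "cultivation.csv": ["block_id", "pasture_age_class", "enterprise", "start_month", "fallow_months"],
    "erosion.csv": [
        "block_id", "land_use", "slope", "season", "cover_factor",
        "land_use_multiplier", "soil_total_n_fraction",
    ],
    "observations.csv": ["obs_id", "land_use", "flow_path", "loss_kg_ha_yr"],
}


class ScenarioError(ValueError):
    """All problems found while loading a scenario, reported together."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("scenario validation failed:\n  - " + "\n  - ".join(self.problems))


def _read(path: Path, name: str, problems: list[str], required: bool) -> pd.DataFrame | None:
    f = path / name
    if not f.exists():
        if required:
            problems.append(f"{name}: file missing")
        return None
    try:
        frame = pd.read_csv(f)
    except Exception as exc:  # malformed CSV
        problems.append(f"{name}: unreadable ({exc})")
        return None
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in frame.columns]
    if missing:
        problems.append(f"{name}: missing columns {missing}")
        return None
    return frame


def load_scenario(path: str | Path) -> FixtureFarm:
    """Load and validate a scenario directory into a FixtureFarm.

    Raises ScenarioError listing every missing file/column, non-numeric cell
    and broken foreign key found, each naming the offending file and value.
    """
    path = Path(path)
    problems: list[str] = []

    blocks_df = _read(path, "blocks.csv", problems, required=True)
    soils_df = _read(path, "soils.csv", problems, required=True)
    climate_df = _read(path, "climate.csv", problems, required=True)
    stock_df = _read(path, "stock.csv", problems, required=False)
    fert_df = _read(path, "fertilizer.csv", problems, required=False)
    products_df = _read(path, "products.csv", problems, required=False)
    rates_df = _read(path, "excreta_rates.csv", problems, required=False)
    crops_df = _read(path, "crops.csv", problems, required=False)
    cult_df = _read(path, "cultivation.csv", problems, required=False)
    erosion_df = _read(path, "erosion.csv", problems, required=False)
    if problems:
        raise ScenarioError(problems)

    cfg = {}
    cfg_path = path / "config.yaml"
    if cfg_path.exists():
        cfg = yaml.safe_load(cfg_path.read_text()) or {}

    soils: dict[str, SoilProfile] = {}
    for soil_id, grp in soils_df.groupby("soil_id"):
        grp = grp.sort_values("layer_index")
        try:
            layers = tuple(
                SoilLayer(
                    float(r.thickness_mm), float(r.theta_sat), float(r.theta_fc),
                    float(r.theta_wp), float(r.drainage_coefficient),
                )
                for r in grp.itertuples()
            )
            soils[str(soil_id)] = SoilProfile(
                str(soil_id), layers,
                runoff_curve_parameter=float(grp["runoff_curve_parameter"].iloc[0]),
                total_n_fraction=float(grp["total_n_fraction"].iloc[0]),
                bulk_density=float(grp["bulk_density"].iloc[0]),
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"soils.csv: soil_id={soil_id}: {exc}")

    climates: dict[str, ClimateSeries] = {}
    for climate_id, grp in climate_df.groupby("climate_id"):
        try:
            grp = grp.sort_values("date")
            climates[str(climate_id)] = ClimateSeries.from_frame(grp)
        except (ValueError, TypeError) as exc:
            problems.append(f"climate.csv: climate_id={climate_id}: {exc}")

    blocks: list[Block] = []
    for r in blocks_df.itertuples():
        try:
            block = Block(
                block_id=str(r.block_id), area_ha=float(r.area_ha), land_use=str(r.land_use),
                soil_id=str(r.soil_id), slope=str(r.slope), climate_id=str(r.climate_id),
                irrigated=bool(r.irrigated),
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"blocks.csv: block_id={r.block_id}: {exc}")
            continue
        if block.soil_id not in soils:
            problems.append(f"blocks.csv: block_id={block.block_id}: unknown soil id {block.soil_id!r}")
        if block.climate_id not in climates:
            problems.append(
                f"blocks.csv: block_id={block.block_id}: unknown climate id {block.climate_id!r}"
            )
        blocks.append(block)

    block_ids = {b.block_id for b in blocks}

    def check_fk(frame: pd.DataFrame | None, name: str) -> None:
        if frame is None or frame.empty:
            return
        unknown = sorted(set(frame["block_id"].astype(str)) - block_ids)
        if unknown:
            problems.append(f"{name}: unknown block ids {unknown}")

    for frame, name in (
        (stock_df, "stock.csv"), (fert_df, "fertilizer.csv"), (crops_df, "crops.csv"),
        (cult_df, "cultivation.csv"), (erosion_df, "erosion.csv"),
    ):
        check_fk(frame, name)

    products = {}
    if products_df is not None:
        products = dict(zip(products_df["product_id"].astype(str), products_df["n_fraction"].astype(float)))
    if fert_df is not None and not fert_df.empty:
        unknown = sorted(set(fert_df["product_id"].astype(str)) - set(products))
        if unknown:
            problems.append(f"fertilizer.csv: unknown product ids {unknown}")

    rates = ExcretaRateTable({})
    if rates_df is not None:
        try:
            rates = ExcretaRateTable.from_frame(rates_df)
        except (ValueError, TypeError, AttributeError) as exc:
            problems.append(f"excreta_rates.csv: {exc}")
    if stock_df is not None and not stock_df.empty:
        keys = {
            (str(r.stock_class), str(r.age_class), str(r.region))
            for r in stock_df.itertuples()
        }
        unknown = sorted(k for k in keys if k not in rates.rates)
        if unknown:
            problems.append(f"stock.csv: no excreta rate for {unknown}")

    if problems:
        raise ScenarioError(problems)

    calendars: dict[str, BlockCalendar] = {}
    for block in blocks:
        bid = block.block_id
        stock_by_month: dict[int, list] = {}
        milking: dict[int, float] = {}
        if stock_df is not None:
            for r in stock_df[stock_df["block_id"].astype(str) == bid].itertuples():
                m = int(r.month)
                entry = (str(r.stock_class), str(r.age_class), str(r.region), float(r.head))
                stock_by_month.setdefault(m, []).append(entry)
                if (entry[0], entry[1]) == MILKING_KEY:
                    milking[m] = milking.get(m, 0.0) + entry[3]
        fert = []
        if fert_df is not None:
            fert = [
                FertilizerApplication(str(r.product_id), float(r.mass_kg_ha), int(r.month))
                for r in fert_df[fert_df["block_id"].astype(str) == bid].itertuples()
            ]
        crops = []
        if crops_df is not None:
            crops = [
                CropRecord(
                    str(r.crop_id), float(r.yield_t_ha), int(r.harvest_month),
                    float(r.residue_fraction_ag), float(r.n_conc_ag_kg_t),
                    float(r.n_conc_bg_kg_t), float(r.cn_ratio), str(r.rooting_class),
                )
                for r in crops_df[crops_df["block_id"].astype(str) == bid].itertuples()
            ]
        cultivation = None
        if cult_df is not None:
            sub = cult_df[cult_df["block_id"].astype(str) == bid]
            if len(sub) > 0:
                r = next(sub.itertuples())
                cultivation = CultivationEvent(
                    str(r.pasture_age_class), str(r.enterprise), int(r.start_month),
                    int(r.fallow_months),
                )
        erosion = []
        if erosion_df is not None:
            erosion = [
                ErosionContext(
                    str(r.land_use), str(r.slope), str(r.season), float(r.cover_factor),
                    float(r.land_use_multiplier), float(r.soil_total_n_fraction),
                )
                for r in erosion_df[erosion_df["block_id"].astype(str) == bid].itertuples()
            ]
        calendars[bid] = BlockCalendar(
            area_ha=block.area_ha, stock_by_month=stock_by_month,
            milking_cows_by_month=milking, fertilizer=fert, crops=crops,
            cultivation=cultivation, erosion=erosion,
        )

    return FixtureFarm(
        blocks=blocks, soils=soils, climates=climates, calendars=calendars,
        excreta_rates=rates, products=products,
        effluent_n_kg_per_cow_month=float(cfg.get("effluent_n_kg_per_cow_month", 0.6)),
    )


def write_scenario(farm: FixtureFarm, path: str | Path) -> None:
    """Write a FixtureFarm out as a scenario directory (inverse of load_scenario)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "block_id": b.block_id, "area_ha": b.area_ha, "land_use": b.land_use,
                "soil_id": b.soil_id, "slope": b.slope, "climate_id": b.climate_id,
                "irrigated": int(b.irrigated),
            }
            for b in farm.blocks
        ]
    ).to_csv(path / "blocks.csv", index=False)

    soil_rows = []
    for soil in farm.soils.values():
        for i, l in enumerate(soil.layers):
            soil_rows.append(
                {
                    "soil_id": soil.soil_id, "layer_index": i, "thickness_mm": l.thickness_mm,
                    "theta_sat": l.theta_sat, "theta_fc": l.theta_fc, "theta_wp": l.theta_wp,
                    "drainage_coefficient": l.drainage_coefficient,
                    "runoff_curve_parameter": soil.runoff_curve_parameter,
                    "total_n_fraction": soil.total_n_fraction, "bulk_density": soil.bulk_density,
                }
            )
    pd.DataFrame(soil_rows).to_csv(path / "soils.csv", index=False)

    climate_rows = []
    for cid, clim in farm.climates.items():
        climate_rows.append(
            pd.DataFrame(
                {
                    "climate_id": cid,
                    "date": clim.dates.strftime("%Y-%m-%d"),
                    "rain_mm": np.round(clim.rain_mm, 6),
                    "pet_mm": np.round(clim.pet_mm, 6),
                }
            )
        )
    pd.concat(climate_rows).to_csv(path / "climate.csv", index=False)

    stock_rows, milk_seen = [], set()
    fert_rows, crop_rows, cult_rows, erosion_rows = [], [], [], []
    for bid, cal in farm.calendars.items():
        for m, entries in sorted(cal.stock_by_month.items()):
            for sc, ac, rg, head in entries:
                stock_rows.append(
                    {"block_id": bid, "month": m, "stock_class": sc, "age_class": ac,
                     "region": rg, "head": head}
                )
        for app in cal.fertilizer:
            fert_rows.append(
                {"block_id": bid, "month": app.month, "product_id": app.product_id,
                 "mass_kg_ha": app.mass_kg_ha}
            )
        for c in cal.crops:
            crop_rows.append(
                {"block_id": bid, "crop_id": c.crop_id, "yield_t_ha": c.yield_t_ha,
                 "harvest_month": c.harvest_month, "residue_fraction_ag": c.residue_fraction_ag,
                 "n_conc_ag_kg_t": c.n_conc_ag_kg_t, "n_conc_bg_kg_t": c.n_conc_bg_kg_t,
                 "cn_ratio": c.cn_ratio, "rooting_class": c.rooting_class}
            )
        if cal.cultivation is not None:
            e = cal.cultivation
            cult_rows.append(
                {"block_id": bid, "pasture_age_class": e.pasture_age_class,
                 "enterprise": e.enterprise, "start_month": e.start_month,
                 "fallow_months": e.fallow_months}
            )
        for ctx in cal.erosion:
            erosion_rows.append(
                {"block_id": bid, "land_use": ctx.land_use, "slope": ctx.slope,
                 "season": ctx.season, "cover_factor": ctx.cover_factor,
                 "land_use_multiplier": ctx.land_use_multiplier,
                 "soil_total_n_fraction": ctx.soil_total_n_fraction}
            )
    pd.DataFrame(stock_rows, columns=REQUIRED_COLUMNS["stock.csv"]).to_csv(path / "stock.csv", index=False)
    pd.DataFrame(fert_rows, columns=REQUIRED_COLUMNS["fertilizer.csv"]).to_csv(path / "fertilizer.csv", index=False)
    pd.DataFrame(crop_rows, columns=REQUIRED_COLUMNS["crops.csv"]).to_csv(path / "crops.csv", index=False)
    pd.DataFrame(cult_rows, columns=REQUIRED_COLUMNS["cultivation.csv"]).to_csv(path / "cultivation.csv", index=False)
    pd.DataFrame(erosion_rows, columns=REQUIRED_COLUMNS["erosion.csv"]).to_csv(path / "erosion.csv", index=False)

    pd.DataFrame(
        [{"product_id": k, "n_fraction": v} for k, v in sorted(farm.products.items())]
    ).to_csv(path / "products.csv", index=False)
    pd.DataFrame(
        [
            {"stock_class": k[0], "age_class": k[1], "region": k[2],
             "urine_n_kg_head_month": u, "dung_n_kg_head_month": d}
            for k, (u, d) in sorted(farm.excreta_rates.rates.items())
        ]
    ).to_csv(path / "excreta_rates.csv", index=False)
    (path / "config.yaml").write_text(
        yaml.safe_dump({"effluent_n_kg_per_cow_month": farm.effluent_n_kg_per_cow_month})
    )


def write_observations(records: Sequence[ObservationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"obs_id": o.obs_id, "land_use": o.land_use, "flow_path": o.flow_path,
             "loss_kg_ha_yr": o.loss_kg_ha_yr, "measured": int(o.measured),
             "n_form": o.n_form, "low_confidence": int(o.low_confidence),
             "location": o.location}
            for o in records
        ]
    ).to_csv(path, index=False)


def load_observations(path: str | Path) -> list[ObservationRecord]:
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS["observations.csv"] if c not in frame.columns]
    if missing:
        raise ScenarioError([f"observations.csv: missing columns {missing}"])
    return [
        ObservationRecord(
            obs_id=str(r.obs_id), land_use=str(r.land_use), flow_path=str(r.flow_path),
            loss_kg_ha_yr=float(r.loss_kg_ha_yr),
            measured=bool(getattr(r, "measured", True)),
            n_form=str(getattr(r, "n_form", "total_n")),
            low_confidence=bool(getattr(r, "low_confidence", False)),
            location=str(getattr(r, "location", "")),
        )
        for r in frame.itertuples()
    ]


def scores_frame(scores: Sequence[RiskScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"block_id": s.block_id, "month": s.month, "leach_index": s.leach_index,
             "runoff_index": s.runoff_index, "total": s.total}
            for s in scores
        ]
    )


def write_risk_report(
    scores: Sequence[RiskScore],
    outdir: str | Path,
    *,
    audit_trails: dict[str, Sequence[ModifierStep]] | None = None,
    validation: RankRegressionResult | None = None,
    block_coords: dict[str, tuple[float, float]] | None = None,
) -> dict[str, Path]:
    """Write the risk report: scores CSV, pathway-share summary, optional audit
    trail CSV, validation CSV/figure and a GeoJSON join when coordinates exist.

    Deterministic: identical inputs reproduce identical bytes.
    """
    if not scores:
        raise ValueError("score set must be non-empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    frame = scores_frame(scores)
    risk_csv = outdir / "risk_scores.csv"
    frame.to_csv(risk_csv, index=False, float_format="%.10g")
    written["risk_scores"] = risk_csv

    shares = aggregate_risk(list(scores), "pathway_shares")
    summary = outdir / "summary.txt"
    summary.write_text(
        "pathway shares: leaching={:.4f} runoff={:.4f}\n".format(
            shares["leach_share"], shares["runoff_share"]
        )
    )
    written["summary"] = summary

    if audit_trails:
        rows = []
        for bid, trail in sorted(audit_trails.items()):
            for step_no, step in enumerate(trail, start=1):
                rows.append(
                    {"block_id": bid, "step": step_no, "modifier": step.name,
                     "pathway": step.pathway, "effectiveness": step.effectiveness,
                     "leach_index_after": step.leach_index_after,
                     "runoff_index_after": step.runoff_index_after}
                )
        audit_csv = outdir / "mitigation_audit.csv"
        pd.DataFrame(rows).to_csv(audit_csv, index=False, float_format="%.10g")
        written["audit"] = audit_csv

    if validation is not None:
        val_csv = outdir / "validation.csv"
        pd.DataFrame(
            [{"slope": validation.slope, "intercept": validation.intercept,
              "r_squared": validation.r_squared, "p_value": validation.p_value,
              "n": validation.n,
              "outside_prediction_band": validation.outside_prediction_band}]
        ).to_csv(val_csv, index=False, float_format="%.10g")
        written["validation"] = val_csv
        fig_path = outdir / "rank_plot.svg"
        write_rank_plot(validation, fig_path)
        written["rank_plot"] = fig_path

    if block_coords:
        annual = frame.groupby("block_id", as_index=False)[["leach_index", "runoff_index", "total"]].sum()
        features = []
        for r in annual.itertuples():
            if r.block_id not in block_coords:
                continue
            lon, lat = block_coords[r.block_id]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [lon, lat]},
                    "properties": {
                        "block_id": r.block_id, "leach_index": r.leach_index,
                        "runoff_index": r.runoff_index, "total": r.total,
                    },
                }
            )
        geo = outdir / "risk_blocks.geojson"
        geo.write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
        )
        written["geojson"] = geo

    return written


def write_rank_plot(result: RankRegressionResult, path: str | Path) -> None:
    """Rank-vs-rank scatter with the fitted line and 95% confidence and
    prediction bands (rank 1 = greatest on both axes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    x, y = result.risk_ranks, result.obs_ranks
    ax.scatter(x, y, s=18, color="k", zorder=3)
    if not result.degenerate:
        order = np.argsort(x)
        xs = np.asarray(x)[order]
        ax.plot(xs, result.intercept + result.slope * xs, color="tab:blue", label="rank OLS")
        for band, style, label in (
            (result.conf_band, "--", "95% CI"),
            (result.pred_band, ":", "95% PI"),
        ):
            b = band.iloc[order]
            ax.plot(b["x"], b["lower"], style, color="tab:blue", lw=1, label=label)
            ax.plot(b["x"], b["upper"], style, color="tab:blue", lw=1)
    ax.set_xlabel("rank of risk score (1 = greatest)")
    ax.set_ylabel("rank of observed N loss (1 = greatest)")
    ax.set_title(f"rank regression: r$^2$={result.r_squared:.2f}, n={result.n}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
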