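"""Table schemas, config loading and the end-to-end pipeline.

Interchange format is plain CSV (UTF-8, header row, '.' decimal).  Output
files carry a provenance header of '#'-prefixed comment lines (package
version, seed, config hash) that the loaders skip, so a written table
round-trips exactly and a recorded config reproduces its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

import gillnetkit
from gillnetkit import gearsurvey, harvest, monitoring, synthio

log = logging.getLogger(__name__)

__all__ = ["SCHEMAS", "RunConfig", "load_table", "write_table", "load_config", "run_pipeline"]

# column name -> dtype; None means any
SCHEMAS: Mapping[str, Mapping[str, str]] = {
    "sets": {
        "set_id": "str", "site": "str", "year": "int", "net": "int",
        "soak_hr": "float", "nights": "int",
    },
    "panels": {"set_id": "str", "mesh_cm": "float", "length_m": "float"},
    "catch": {
        "set_id": "str", "mesh_cm": "float", "species": "str",
        "length_mm": "float", "weight_g": "float",
    },
    "transects": {
        "transect_id": "str", "site": "str", "year": "int", "length_km": "float",
    },
    "items": {"transect_id": "str", "category": "str", "weight_g": "float", "mesh_cm": "float"},
    "life_history": {
        "species": "str", "linf_cm": "float", "k": "float", "t0": "float",
        "t_max": "float", "gsi": "float",
    },
}

# columns in which missing values are meaningful, not errors
_NULLABLE = {"catch": {"weight_g"}, "items": {"mesh_cm", "weight_g"}}


class SchemaError(ValueError):
    pass


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Provenance comment lines ('#'-prefixed) are skipped.  Missing
    required columns, or unparsable values in non-nullable columns, raise
    :class:`SchemaError` naming the column (and the first offending data
    row, counted from the top of the file).
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    nullable = _NULLABLE.get(schema, set())
    for col, dtype in spec.items():
        if dtype == "str":
            df[col] = df[col].astype(str)
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise SchemaError(
                f"{path.name}: column {col!r} has unparsable value "
                f"{df[col][bad.idxmax()]!r} near line {row}"
            )
        if coerced.isna().any() and col not in nullable:
            row = int(coerced.isna().idxmax()) + 2
            raise SchemaError(f"{path.name}: column {col!r} empty near line {row}")
        df[col] = coerced.astype(int) if dtype == "int" else coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, provenance: Mapping | None = None) -> None:
    """Write a CSV with a '#'-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# gillnetkit {gillnetkit.__version__}"]
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Paths, assessment inputs and switches for one pipeline run."""

    out_dir: Path
    seed: int = 0
    catch: Path | None = None
    sets: Path | None = None
    panels: Path | None = None
    items: Path | None = None
    transects: Path | None = None
    life_history: Path | None = None
    species: list[str] = field(default_factory=list)
    responses: list[str] = field(default_factory=lambda: ["abundance"])
    mesh_bins: list[float] | None = None
    assessment: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True,
        )
        return {
            "seed": self.seed,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest()[:16],
        }


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    paths = raw.get("inputs", {})
    cfg = RunConfig(
        out_dir=Path(raw.get("out_dir", "out")),
        seed=int(raw.get("seed", 0)),
        species=list(raw.get("species", [])),
        responses=list(raw.get("responses", ["abundance"])),
        mesh_bins=raw.get("mesh_bins"),
        assessment=dict(raw.get("assessment", {})),
    )
    for key in ("catch", "sets", "panels", "items", "transects", "life_history"):
        if key in paths:
            cfg.__dict__[key] = Path(paths[key])
    return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage the config enables; return a summary dict.

    Stages: gear survey (items + transects), CPUE/trends (catch + sets +
    panels), assessment (life-history table + assessment inputs).  Each
    stage failure aborts with the stage name attached.  Outputs are
    deterministic given the config and seed.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    prov = cfg.provenance()
    summary: dict = {"seed": cfg.seed, "stages": []}

    if cfg.items is not None and cfg.transects is not None:
        try:
            summary["gear_survey"] = _gear_stage(cfg, prov)
            summary["stages"].append("gear_survey")
        except Exception as err:
            raise RuntimeError(f"stage gear_survey failed: {err}") from err

    if cfg.catch is not None and cfg.sets is not None and cfg.panels is not None:
        try:
            summary["trends"] = _trend_stage(cfg, prov)
            summary["stages"].append("trends")
        except Exception as err:
            raise RuntimeError(f"stage trends failed: {err}") from err

    if cfg.life_history is not None or cfg.assessment.get("m_estimates"):
        try:
            summary["assessment"] = _assessment_stage(cfg, prov)
            summary["stages"].append("assessment")
        except Exception as err:
            raise RuntimeError(f"stage assessment failed: {err}") from err

    with open(cfg.out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def _gear_stage(cfg: RunConfig, prov: Mapping) -> dict:
    items = load_table(cfg.items, "items")
    transects = load_table(cfg.transects, "transects")
    records = []
    for t in transects.itertuples(index=False):
        tr = gearsurvey.Transect(
            transect_id=t.transect_id, site=t.site, year=int(t.year),
            length_km=float(t.length_km),
        )
        sub = items[items["transect_id"] == t.transect_id]
        for scope in ("all", "gillnet"):
            r = gearsurvey.transect_density(sub, tr, scope=scope)
            records.append(
                {
                    "transect_id": r.transect_id, "site": t.site, "year": int(t.year),
                    "scope": r.scope, "count": r.count,
                    "count_per_km": r.count_density, "g_per_km": r.weight_density,
                }
            )
    dens = pd.DataFrame(records)
    write_table(dens, cfg.out_dir / "gear_densities.csv", prov)
    comp = gearsurvey.mesh_composition(items, cfg.mesh_bins)
    write_table(comp, cfg.out_dir / "mesh_composition.csv", prov)
    pooled = {}
    for scope in ("all", "gillnet"):
        recs = [
            gearsurvey.DensityRecord(
                transect_id=r["transect_id"], scope=r["scope"], count=r["count"],
                count_density=r["count_per_km"], weight_density=r["g_per_km"],
                length_km=float(
                    transects.set_index("transect_id")["length_km"][r["transect_id"]]
                ),
            )
            for r in records
            if r["scope"] == scope
        ]
        p = gearsurvey.pooled_density(recs)
        pooled[scope] = {"count_per_km": p.count_density, "g_per_km": p.weight_density}
    return {"pooled": pooled, "n_items": int(len(items))}


def _trend_stage(cfg: RunConfig, prov: Mapping) -> dict:
    catch = load_table(cfg.catch, "catch")
    sets = load_table(cfg.sets, "sets")
    panels = load_table(cfg.panels, "panels")
    species = cfg.species or sorted(catch["species"].unique())
    out: dict = {}
    rows = []
    for sp in species:
        sub = catch[catch["species"] == sp]
        try:
            lw = monitoring.fit_length_weight(sub)
        except ValueError:
            lw = None
        if lw is not None:
            sub = monitoring.impute_weights(sub, {sp: lw})
        table = monitoring.panel_cpue_table(sub, sets, panels)
        per_set = (
            table.groupby("set_id")[["n", "kg"]].sum().reset_index()
            .merge(sets[["set_id", "site", "year", "nights"]], on="set_id")
        )
        per_set["cpue_count"] = per_set["n"] / per_set["nights"]
        per_set["cpue_kg"] = per_set["kg"] / per_set["nights"]
        entry: dict = {}
        if lw is not None:
            entry["lw"] = {"a": lw.a, "b": lw.b, "n": lw.n}
        try:
            entry["optimal_mesh_count"] = monitoring.optimal_mesh(table, "count")
            entry["optimal_mesh_biomass"] = monitoring.optimal_mesh(table, "biomass")
        except ValueError:
            pass
        for resp in cfg.responses:
            col = {"abundance": "cpue_kg", "length": "length_mm", "weight": "weight_g"}[resp]
            data = per_set if resp == "abundance" else (
                sub.merge(sets[["set_id", "site", "year"]], on="set_id")
            )
            if resp == "weight":
                data = data[~data.get("weight_imputed", pd.Series(False, index=data.index))]
            try:
                tr = monitoring.trend_test(data, col)
            except ValueError as err:
                entry[f"trend_{resp}"] = {"error": str(err)}
                continue
            entry[f"trend_{resp}"] = {
                "slope": tr.slope, "se": tr.slope_se, "p": tr.p_value, "n": tr.n_obs,
            }
            rows.append({"species": sp, "response": resp, **entry[f"trend_{resp}"]})
        out[sp] = entry
    if rows:
        write_table(pd.DataFrame(rows), cfg.out_dir / "trends.csv", prov)
    return out


def _assessment_stage(cfg: RunConfig, prov: Mapping) -> dict:
    a = cfg.assessment
    inputs = harvest.AssessmentInputs(
        z=float(a.get("z", 0.42)),
        biomass_density_kg_ha=float(a.get("biomass_density_kg_ha", 4.4)),
        area_ha=float(a.get("area_ha", 276_000)),
        catch_per_night_kg=float(a.get("catch_per_night_kg", 15.0)),
        nights_per_fisher_year=float(a.get("nights_per_fisher_year", 100.0)),
        population=float(a.get("population", 5_440)),
        household_size=float(a.get("household_size", 3.6)),
    )
    if a.get("m_estimates"):
        m_src: dict | synthio.LifeHistory = {
            k: float(v) for k, v in a["m_estimates"].items()
        }
    else:
        lh_table = load_table(cfg.life_history, "life_history")
        target = a.get("species", lh_table["species"].iloc[0])
        row = lh_table[lh_table["species"] == target].iloc[0]
        m_src = synthio.LifeHistory(
            linf=float(row.linf_cm), k=float(row.k), t0=float(row.t0),
            t_max=float(row.t_max), gsi=float(row.gsi),
        )
    table = harvest.assessment_table(m_src, inputs)
    write_table(table, cfg.out_dir / "assessment_full.csv", prov)
    display = harvest.assessment_report(table)
    write_table(display, cfg.out_dir / "assessment_display.csv", prov)
    return {
        "biomass_kg": inputs.biomass_kg,
        "rows": display.to_dict(orient="records"),
    }
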