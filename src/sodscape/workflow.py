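"""Run orchestration: landscape suites, assay batteries, correlation stage.

A :class:`RunConfig` fully determines a run; it is serialized into a JSON
manifest next to every output so any run can be replayed from its manifest
alone.  Output file names are content-stable (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from sodscape import assay_fits, correlations, synthetic_data
from sodscape.bwsme_engine import (
    VARIANT_NAMES,
    BlockScheme,
    EnergyParams,
    VariantScheme,
    calibrate_xi,
    early_folding_region,
    ensemble,
    region_overlap,
    stability,
)
from sodscape.structure_contacts import (
    assign_charges,
    build_contact_map,
    read_structure,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run.

    ``structure`` is either ``"toy:<kind>"`` (synthetic structure) or a PDB
    path; ``xi`` of None means iso-stability calibration at
    ``target_stability`` J/mol.  Unknown keys in :meth:`from_dict` are
    rejected so manifests cannot silently drift.
    """

    structure: str = "toy:two_loop_protein"
    chain: str = "A"
    variants: tuple[str, ...] = VARIANT_NAMES
    block_length: int = 3
    xi: float | None = None
    target_stability: float = 25_000.0
    temperature: float = 298.0
    contact_cutoff: float = 6.0
    min_separation: int = 2
    loop_zn: tuple[int, int] | None = None
    loop_cu: tuple[int, int] | None = None
    calibration_bracket: tuple[float, float] = (-12_000.0, 0.0)
    out_dir: str = "sodscape_run"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for v in cfg.variants:
            if v not in VARIANT_NAMES:
                raise ValueError(f"unknown variant {v!r}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_structure(config: RunConfig):
    if config.structure.startswith("toy:"):
        kind = config.structure.split(":", 1)[1]
        return synthetic_data.toy_structure(kind)
    path = Path(config.structure)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    return read_structure(path, config.chain)


def _variant_scheme(config: RunConfig, name: str) -> VariantScheme:
    kwargs = {}
    if config.structure == "toy:two_loop_protein":
        kwargs["loop_zn"] = synthetic_data.TOY_LOOP_ZN
        kwargs["loop_cu"] = synthetic_data.TOY_LOOP_CU
    if config.loop_zn is not None:
        kwargs["loop_zn"] = tuple(config.loop_zn)
    if config.loop_cu is not None:
        kwargs["loop_cu"] = tuple(config.loop_cu)
    return VariantScheme(name, **kwargs)


def run_landscape_suite(config: RunConfig) -> dict:
    """Per-variant landscape: calibrated (or fixed-xi) ensemble, CSV outputs,
    and a cross-variant summary of early-folding regions."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = _load_structure(config)
    cm = build_contact_map(s, cutoff=config.contact_cutoff,
                           min_separation=config.min_separation)
    q = assign_charges(s)
    bs = BlockScheme.from_block_length(s.n_residues, config.block_length)
    positions = s.sequence_ids()

    results, xis, regions = {}, {}, {}
    for name in config.variants:
        vs = _variant_scheme(config, name)
        p = EnergyParams(T=config.temperature)
        if config.xi is None:
            xi = calibrate_xi(
                cm, q, bs, vs, p,
                target_stability=config.target_stability,
                bracket=config.calibration_bracket,
                residue_positions=positions,
            )
        else:
            xi = config.xi
        p = replace(p, xi=xi)
        res = ensemble(cm, q, bs, vs, p, residue_positions=positions)
        results[name] = res
        xis[name] = xi
        regions[name] = early_folding_region(res)

        pd.DataFrame(
            {"residue": positions, "P_fold": res.P_fold}
        ).to_csv(out / f"{name}_pfold.csv", index=False)
        pm = pd.DataFrame(
            res.P_matrix,
            index=pd.Index(positions, name="residue"),
            columns=[f"n{k}" for k in range(res.n_blocks + 1)],
        )
        pm.to_csv(out / f"{name}_pmatrix.csv")
        pd.DataFrame(
            {"n_blocks": np.arange(res.n_blocks + 1), "F_J_mol": res.profile}
        ).to_csv(out / f"{name}_profile.csv", index=False)

    summary = {
        "xi": xis,
        "stability_J_mol": {
            name: stability(results[name], EnergyParams(T=config.temperature, xi=xis[name]))
            for name in results
        },
        "early_folding_regions": {
            name: sorted(positions[i] for i in regions[name]) for name in regions
        },
    }
    if "holo" in regions:
        overlaps = {
            name: region_overlap(regions[name], regions["holo"])
            for name in regions
        }
        summary["overlap_with_holo"] = overlaps
        if "apo" in overlaps:
            summary["apo_pathway_differs_from_holo"] = bool(overlaps["apo"] < 0.5)
    manifest = {"config": config.to_dict(), "summary": summary}
    (out / "landscape_summary.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float)
    )
    return {"results": results, "summary": summary}


# ---------------------------------------------------------------------------
# assay battery

#: battery file naming convention: <protein>__<assay>.csv
BATTERY_ASSAYS = (
    "stern_volmer_free",
    "stern_volmer_bound",
    "unfolding",
    "fcs",
    "binding",
    "tht",
    "leakage",
    "guv",
    "ftir",
)


def _fit_battery_file(assay: str, df: pd.DataFrame) -> dict:
    if assay in ("stern_volmer_free", "stern_volmer_bound"):
        r = assay_fits.stern_volmer_fit(df["conc_M"], df["signal"])
        return {"K_sv": r.K_sv, "intercept": r.intercept}
    if assay == "unfolding":
        r = assay_fits.two_state_unfolding_fit(df["conc_M"], df["signal"])
        return {"dG0": r.dG0, "m": r.m, "Cm": r.Cm}
    if assay == "fcs":
        r = assay_fits.fcs_fit(df["tau_s"], df["G"], n_components=2)
        return {
            "N": r.N,
            "fractions": [c.fraction for c in r.components],
            "tau_D": [c.tau_D for c in r.components],
        }
    if assay == "binding":
        r = assay_fits.binding_isotherm_fit(df["conc_M"], df["bound_percent"])
        return {"Ka": r.Ka, "hill": r.hill}
    if assay == "tht":
        r = assay_fits.tht_kinetics_fit(df["time_h"], df["signal"])
        return {"t50": r.t50, "lag": r.lag, "label": r.label,
                "detectable": r.detectable}
    if assay == "leakage":
        r = assay_fits.leakage_rate(df["time_s"], df["signal"])
        return {"rate": r.rate, "flat": r.flat}
    if assay == "guv":
        t, stack = synthetic_data.guv_profile_stack(df)
        r = assay_fits.guv_deformation(t, stack)
        return {"lambda": r.lambda_rate, "detectable": r.detectable}
    if assay == "ftir":
        r = assay_fits.ftir_deconvolve(df["wavenumber_cm1"], df["absorbance"])
        return {"fractions": r.fractions,
                "peak_positions": r.peak_positions}
    raise ValueError(f"unknown battery assay {assay!r}")


def run_assay_battery(input_dir, out_dir) -> dict:
    """Fit every ``<protein>__<assay>.csv`` under ``input_dir``.

    Produces one JSON report per file, a quenching-ratio table (K_sv free vs
    membrane-bound, with the 2-dp reporting ratio), and a ThT midpoint table
    in which undetectable traces read "Not detectable".  Per-file failures
    are collected and reported; the run continues past them.
    """
    input_dir = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = sorted(input_dir.glob("*__*.csv"))
    if not files:
        raise ValueError(f"no battery files (<protein>__<assay>.csv) in {input_dir}")

    fits: dict[str, dict[str, dict]] = {}
    failures: dict[str, str] = {}
    for f in files:
        protein, assay = f.stem.split("__", 1)
        if assay not in BATTERY_ASSAYS:
            failures[f.name] = f"unknown assay {assay!r}"
            continue
        try:
            fits.setdefault(protein, {})[assay] = _fit_battery_file(
                assay, pd.read_csv(f)
            )
        except Exception as exc:  # noqa: BLE001 - collected per file
            failures[f.name] = str(exc)
            logger.error("battery fit failed for %s: %s", f.name, exc)

    ratio_rows = []
    for protein, by_assay in sorted(fits.items()):
        free = by_assay.get("stern_volmer_free")
        bound = by_assay.get("stern_volmer_bound")
        if free and bound:
            raw, rounded = assay_fits.quench_ratio(free["K_sv"], bound["K_sv"])
            ratio_rows.append(
                (protein, free["K_sv"], bound["K_sv"], raw, rounded)
            )
    ratio_table = pd.DataFrame(
        ratio_rows, columns=["protein", "K_sv", "K_svm", "ratio_raw", "ratio"]
    )

    midpoint_rows = [
        (protein, by_assay["tht"]["label"])
        for protein, by_assay in sorted(fits.items())
        if "tht" in by_assay
    ]
    midpoint_table = pd.DataFrame(
        midpoint_rows, columns=["protein", "log_phase_midpoint_h"]
    )

    ratio_table.to_csv(out / "quench_ratios.csv", index=False)
    midpoint_table.to_csv(out / "tht_midpoints.csv", index=False)
    report = {"fits": fits, "failures": failures}
    (out / "battery_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float)
    )
    return {
        "fits": fits,
        "failures": failures,
        "ratio_table": ratio_table,
        "midpoint_table": midpoint_table,
    }


def run_correlation_stage(table_path=None, survival_path=None, out_path=None) -> dict:
    """Distance/energy/survival trends from the mutant table."""
    records = correlations.load_table5(table_path)
    trends = correlations.distance_energy_trends(records)
    survival = correlations.load_survival(survival_path)
    sev = correlations.severity_join(records, survival)
    report = {
        "n_mutants": len(records),
        "zn_distance_vs_dG": dataclasses.asdict(trends["zn"]),
        "cu_distance_vs_dG": dataclasses.asdict(trends["cu"]),
        "zn_distance_vs_survival": dataclasses.asdict(sev),
        "zn_dominates_cu": bool(
            abs(trends["zn"].pearson_r) > abs(trends["cu"].pearson_r)
        ),
    }
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float)
        )
    return report
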