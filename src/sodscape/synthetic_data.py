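"""Synthetic inputs for every pipeline stage.

Two kinds of artifacts are generated, both fully deterministic given a seed:

* toy protein structures (ideal-geometry helix, beta hairpin, and a
  "two-loop protein" that mimics the architecture the folding model cares
  about: a core segment plus two designated metal-binding loops packed
  against pseudo-Zn and pseudo-Cu sites), and
* tidy assay datasets drawn exactly from the corresponding fit models plus
  stated Gaussian noise -- Stern-Volmer titrations, two-state melts, FCS
  autocorrelations, binding isotherms, ThT time courses, calcein-leakage
  traces, GUV line-profile stacks, and amide-I spectra.

Default generator parameters are the values reported for SOD1 and its
variants (e.g. WT K_sv = 6.8 M^-1, apo ThT midpoint 112.8 h, free-monomer
hydrodynamic radius 13.5 A); every dataset ships with a manifest recording
the exact truth used, so recovery tests can compare against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sodscape import assay_fits
from sodscape.structure_contacts import MetalSite, ProteinStructure, Residue

# designated loop ranges of the two-loop toy protein (1-based, n = 60):
# a 20-residue "Zn loop" and a 10-residue "Cu loop", mirroring the size
# asymmetry of SOD1's loop IV (34 residues) vs loop VII (22 residues).
TOY_N_RESIDUES = 60
TOY_LOOP_ZN = (21, 40)
TOY_LOOP_CU = (51, 60)


# ---------------------------------------------------------------------------
# toy structures


def _helix_coords(n: int, rise: float = 1.5, radius: float = 2.3,
                  twist_deg: float = 100.0) -> np.ndarray:
    k = np.arange(n)
    ang = np.deg2rad(twist_deg) * k
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * k]
    )


def _hairpin_coords(n: int, spacing: float = 4.8, rise: float = 3.5) -> np.ndarray:
    """Two antiparallel strands ``spacing`` apart joined by a 2-residue turn."""
    half = (n - 2) // 2
    up = np.column_stack([np.zeros(half), rise * np.arange(half), np.zeros(half)])
    turn_y = rise * half
    turn = np.array(
        [[spacing * 0.25, turn_y + 1.8, 0.0], [spacing * 0.75, turn_y + 1.8, 0.0]]
    )
    n_down = n - half - 2
    down = np.column_stack(
        [
            np.full(n_down, spacing),
            rise * (half - 1 - np.arange(n_down)),
            np.zeros(n_down),
        ]
    )
    return np.vstack([up, turn, down])


def _as_structure(coords: np.ndarray, metals: list[MetalSite],
                  res_name: str = "ALA") -> ProteinStructure:
    residues = [
        Residue(seq_id=i + 1, name=res_name, chain="A",
                atoms=(("CA", float(x), float(y), float(z)),))
        for i, (x, y, z) in enumerate(coords)
    ]
    return ProteinStructure(residues=residues, metal_sites=metals)


def toy_structure(kind: str, n_residues: int = TOY_N_RESIDUES) -> ProteinStructure:
    """Deterministic ideal-geometry toy structure.

    ``hairpin`` and ``helix`` are single secondary-structure elements;
    ``two_loop_protein`` is a helical core with two hairpin "loops"
    (residues ``TOY_LOOP_ZN`` and ``TOY_LOOP_CU`` for the default size)
    carrying one Zn-like and one Cu-like pseudo-metal site each, so the
    metal-occupancy entropy schemes have designated targets.
    """
    if n_residues < 6:
        raise ValueError("toy structures need at least 6 residues")
    if kind == "helix":
        return _as_structure(_helix_coords(n_residues), [])
    if kind == "hairpin":
        return _as_structure(_hairpin_coords(n_residues), [])
    if kind == "two_loop_protein":
        if n_residues != TOY_N_RESIDUES:
            raise ValueError(
                f"two_loop_protein is defined for n_residues={TOY_N_RESIDUES}"
            )
        # compact serpentine beta-meander: 6 antiparallel rows of 10 residues
        # stacked 4.8 A apart, every residue in contact with the next row, so
        # folding is cooperative (no dead, contact-free segments).  Rows 3-4
        # are the "Zn loop" (interior, hence the densest region), row 6 the
        # "Cu loop"; pseudo-metal sites sit against their loops.
        n_rows, width = 6, 10
        d_col, d_row = 3.5, 4.8
        coords = np.zeros((n_rows * width, 3))
        for r in range(n_rows):
            cols = np.arange(width) if r % 2 == 0 else np.arange(width - 1, -1, -1)
            coords[r * width : (r + 1) * width, 0] = d_col * cols
            coords[r * width : (r + 1) * width, 1] = d_row * r
        zn_center = np.array([d_col * (width - 1) / 2.0, d_row * 2.5, 3.0])
        cu_center = np.array([d_col * (width - 1) / 2.0, d_row * 5.0, 3.0])
        metals = [
            MetalSite("Zn", *map(float, zn_center)),
            MetalSite("Cu", *map(float, cu_center)),
        ]
        return _as_structure(coords, metals)
    raise ValueError(f"unknown toy structure kind {kind!r}")


# ---------------------------------------------------------------------------
# assay generators


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic assay dataset.

    ``params`` override the per-assay defaults (the study's reported values);
    ``noise`` is the Gaussian sigma in the units stated per assay; a seed is
    mandatory whenever noise > 0.
    """

    kind: str
    params: dict = field(default_factory=dict)
    noise: float | None = None
    n_points: int | None = None
    seed: int | None = None

    def resolved(self) -> dict:
        defaults, default_noise, default_n = _ASSAY_DEFAULTS[self.kind]
        p = dict(defaults)
        unknown = set(self.params) - set(defaults)
        if unknown:
            raise ValueError(f"unknown parameters for {self.kind}: {sorted(unknown)}")
        p.update(self.params)
        noise = default_noise if self.noise is None else self.noise
        n = default_n if self.n_points is None else self.n_points
        if noise > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise > 0")
        return {"params": p, "noise": noise, "n_points": n, "seed": self.seed}


_ASSAY_DEFAULTS: dict[str, tuple[dict, float, int]] = {
    # kind: (true parameters, noise sigma, n points)
    "stern_volmer": ({"K_sv": 6.8, "Q_max": 0.3}, 0.02, 10),
    "unfolding": (
        {"dG0": 3.0, "m": 1.5, "yn": 1.0, "mn": 0.0, "yd": 0.0, "md": 0.0,
         "x_max": 6.0},
        0.01, 40,
    ),
    "fcs": (
        {"N": 5.0, "S": 5.0, "f_fast": 0.7, "tau_fast": 1.2e-4,
         "tau_slow": 1.5e-3, "n_components": 2},
        0.005, 120,  # noise relative to G(0) - 1
    ),
    "binding": ({"Ka": 4.1e6, "hill": 1.0, "L_min": 1e-9, "L_max": 1e-5}, 3.0, 12),
    "tht": (
        {"t50": 112.8, "tau": 8.0, "F0": 5.0, "Finf": 105.0, "t_max": 350.0},
        0.02, 60,  # noise relative to amplitude
    ),
    "leakage": ({"rate": 3.5e-3, "F0": 10.0, "amplitude": 90.0, "t_max": 1500.0},
                0.01, 50),  # noise relative to amplitude
    "guv": (
        {"lambda": 1.8e-3, "t50": 1500.0, "I0": 80.0, "Iinf": 5.0,
         "t_max": 3000.0, "n_lines": 3, "profile_points": 81},
        0.01, 25,  # noise relative to I0, per profile point
    ),
    "ftir": (
        {"beta_area": 38.0, "helix_area": 10.0, "disorder_area": 26.0,
         "turns_area": 26.0, "beta_center": 1636.0, "helix_center": 1652.0,
         "disorder_center": 1644.0, "turns_center": 1667.0, "sigma_cm": 3.0},
        0.003, 201,  # noise relative to spectrum maximum
    ),
}

ASSAY_KINDS = tuple(_ASSAY_DEFAULTS)


def _simulate(kind: str, p: dict, n: int, noise: float,
              rng: np.random.Generator) -> pd.DataFrame:
    if kind == "stern_volmer":
        Q = np.linspace(0.0, p["Q_max"], n)
        y = 1.0 + p["K_sv"] * Q
        y = y + (rng.normal(0.0, noise, n) if noise > 0 else 0.0)
        return pd.DataFrame({"conc_M": Q, "signal": y})
    if kind == "unfolding":
        x = np.linspace(0.0, p["x_max"], n)
        e = np.exp(-(p["dG0"] - p["m"] * x) / assay_fits.RT_UNFOLD)
        y = ((p["yn"] + p["mn"] * x) + (p["yd"] + p["md"] * x) * e) / (1.0 + e)
        y = y + (rng.normal(0.0, noise, n) if noise > 0 else 0.0)
        return pd.DataFrame({"conc_M": x, "signal": y})
    if kind == "fcs":
        tau = np.logspace(-6, 0, n)
        if int(p["n_components"]) == 1:
            fractions, taus = [1.0], [p["tau_fast"]]
        else:
            fractions = [p["f_fast"], 1.0 - p["f_fast"]]
            taus = [p["tau_fast"], p["tau_slow"]]
        G = assay_fits.fcs_model(tau, p["N"], fractions, taus, p["S"])
        sigma = noise * (1.0 / p["N"])
        G = G + (rng.normal(0.0, sigma, n) if noise > 0 else 0.0)
        return pd.DataFrame({"tau_s": tau, "G": G})
    if kind == "binding":
        L = np.logspace(math.log10(p["L_min"]), math.log10(p["L_max"]), n)
        z = np.power(p["Ka"] * L, p["hill"])
        b = 100.0 * z / (1.0 + z)
        b = b + (rng.normal(0.0, noise, n) if noise > 0 else 0.0)
        return pd.DataFrame({"conc_M": L, "bound_percent": np.clip(b, 0.0, 100.0)})
    if kind == "tht":
        t = np.linspace(0.0, p["t_max"], n)
        amp = p["Finf"] - p["F0"]
        F = p["F0"] + amp / (1.0 + np.exp((p["t50"] - t) / p["tau"])) if amp != 0 \
            else np.full(n, p["F0"])
        F = F + (rng.normal(0.0, noise * max(abs(amp), 1.0), n) if noise > 0 else 0.0)
        return pd.DataFrame({"time_h": t, "signal": F})
    if kind == "leakage":
        t = np.linspace(0.0, p["t_max"], n)
        F = p["F0"] + p["amplitude"] * (1.0 - np.exp(-p["rate"] * t))
        F = F + (rng.normal(0.0, noise * p["amplitude"], n) if noise > 0 else 0.0)
        return pd.DataFrame({"time_s": t, "signal": F})
    if kind == "guv":
        t = np.linspace(0.0, p["t_max"], n)
        amp_t = p["Iinf"] + (p["I0"] - p["Iinf"]) / (
            1.0 + np.exp(p["lambda"] * (t - p["t50"]))
        )
        x = np.linspace(-1.0, 1.0, int(p["profile_points"]))
        halo = np.exp(-0.5 * ((np.abs(x) - 0.8) / 0.06) ** 2)
        rows = []
        for ti, ai in zip(t, amp_t):
            for line in range(int(p["n_lines"])):
                prof = ai * halo
                if noise > 0:
                    prof = prof + rng.normal(0.0, noise * p["I0"], x.size)
                rows.append(
                    pd.DataFrame(
                        {"time_s": ti, "line": line, "position": x,
                         "intensity": prof}
                    )
                )
        return pd.concat(rows, ignore_index=True)
    if kind == "ftir":
        w = np.linspace(1600.0, 1700.0, n)
        bands = [
            (p["beta_center"], p["beta_area"]),
            (p["helix_center"], p["helix_area"]),
            (p["disorder_center"], p["disorder_area"]),
            (p["turns_center"], p["turns_area"]),
        ]
        s = p["sigma_cm"]
        a = np.zeros(n)
        for c, area in bands:
            a += area / (s * math.sqrt(2 * math.pi)) * np.exp(
                -0.5 * ((w - c) / s) ** 2
            )
        if noise > 0:
            a = a + rng.normal(0.0, noise * a.max(), n)
        return pd.DataFrame({"wavenumber_cm1": w, "absorbance": a})
    raise ValueError(f"unknown assay kind {kind!r}")


def generate(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Draw one dataset from the fit model of ``spec.kind`` plus noise.

    Returns the tidy data frame and a manifest dict recording the full truth
    (parameters, noise, n, seed) for downstream recovery testing.
    """
    if spec.kind not in _ASSAY_DEFAULTS:
        raise ValueError(
            f"unknown assay kind {spec.kind!r}; known: {sorted(_ASSAY_DEFAULTS)}"
        )
    r = spec.resolved()
    rng = np.random.default_rng(r["seed"])
    df = _simulate(spec.kind, r["params"], r["n_points"], r["noise"], rng)
    manifest = {
        "kind": spec.kind,
        "truth": r["params"],
        "noise": r["noise"],
        "n_points": r["n_points"],
        "seed": r["seed"],
    }
    return df, manifest


def write_dataset(spec: GeneratorSpec, out_csv) -> tuple[Path, Path]:
    """Generate and write ``<out>.csv`` plus ``<out>.manifest.json``."""
    df, manifest = generate(spec)
    out_csv = Path(out_csv)
    df.to_csv(out_csv, index=False)
    man_path = out_csv.with_suffix(".manifest.json")
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_csv, man_path


def guv_profile_stack(df: pd.DataFrame) -> tuple[np.ndarray, list[list[np.ndarray]]]:
    """Reshape a tidy GUV dataset into (times, per-time list of line profiles)."""
    times = np.sort(df["time_s"].unique())
    stack = []
    for ti in times:
        sub = df[df["time_s"] == ti]
        stack.append(
            [g["intensity"].to_numpy() for _, g in sub.groupby("line", sort=True)]
        )
    return times, stack
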