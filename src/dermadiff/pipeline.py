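"""Parameter sweeps, the free-vs-effective diffusivity comparison, config I/O.

`run_sweep` simulates the passage curve for every (particle diameter,
viscosity) grid cell in the equivalent capillary, fits the Hill model to
each curve and tabulates the fitted effective diffusivities;
`build_comparison` sets those against the diameter-form Stokes-Einstein
free value and their ratio.  Configurations are declarative YAML with
explicit units.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from importlib import metadata, resources
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import BrickMortarGeometry, build_capillary
from .hill import fit_hill
from .physics import Fluid, ParticleSpec, stokes_einstein_printed
from .simulate import (
    PassageCurve,
    SimulationConfig,
    mean_first_passage_time,
    run_simulation,
)

__all__ = [
    "SweepSpec",
    "default_sweep_spec",
    "run_sweep",
    "build_comparison",
    "load_config",
    "dump_config",
    "plot_passage_curves",
]

logger = logging.getLogger("dermadiff")

#: Reference skin-patch parameters: 2 cm patch, 20 um keratinocytes,
#: 50 nm lipid channels, 10 um keratinocyte height, 1 um capillary.
REFERENCE_GEOMETRY = dict(L=0.02, a=2e-5, d=5e-8, h_k=1e-5)
REFERENCE_CAPILLARY_LENGTH = 1e-6

#: Temperature at which the published free-vs-effective comparison is
#: numerically consistent (the diameter-form Stokes-Einstein column).
COMPARISON_TEMPERATURE = 293.0


@dataclass(frozen=True)
class SweepSpec:
    """Grid of particle diameters x viscosities sharing one run template.

    ``t_end_factor`` sizes each cell's run as that multiple of the cell's
    analytic mean first-passage time (``template.t_end`` is used verbatim
    when ``t_end_factor`` is None).  Cell seeds are ``seed + cell index`` in
    row-major (diameter-major) order.
    """

    diameters: Sequence[float]
    viscosities: Sequence[float]
    template: SimulationConfig
    output_dir: Optional[Path] = None
    seed: int = 0
    t_end_factor: Optional[float] = 20.0

    def __post_init__(self) -> None:
        if len(self.diameters) == 0 or len(self.viscosities) == 0:
            raise ValueError("diameter and viscosity grids must be non-empty")
        if any(d <= 0 for d in self.diameters) or any(v <= 0 for v in self.viscosities):
            raise ValueError("diameters and viscosities must be positive")


def default_sweep_spec(
    n_particles: int = 1000,
    seed: int = 0,
    output_dir: Optional[Union[str, Path]] = None,
    diameters: Sequence[float] = (1e-9, 5e-9, 10e-9, 15e-9),
    viscosities: Sequence[float] = (0.01, 0.02, 0.05),
) -> SweepSpec:
    """Sweep over the reference capillary with the study's parameter grid."""
    geom = BrickMortarGeometry.square(**REFERENCE_GEOMETRY)
    cap = build_capillary(geom, REFERENCE_CAPILLARY_LENGTH)
    template = SimulationConfig(
        capillary=cap,
        particle=ParticleSpec(d_p=1e-9, rho_p=2200.0),
        fluid=Fluid(eta=0.01, rho_f=1000.0, T=298.0),
        n_particles=n_particles,
        t_end=500.0,
        seed=seed,
    )
    return SweepSpec(
        diameters=tuple(diameters),
        viscosities=tuple(viscosities),
        template=template,
        output_dir=None if output_dir is None else Path(output_dir),
        seed=seed,
    )


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Simulate + Hill-fit every grid cell; return one row per cell.

    Columns: ``d_p_nm, eta_mPas, D_eff_m2_per_s, n, r_squared`` (plus
    ``skipped``/``reason`` rows for cells whose particle does not fit the
    capillary).  With an ``output_dir``, writes ``deff_table.csv`` and one
    passage-curve CSV per cell.  Deterministic given the spec's seeds.
    """
    t0 = time.monotonic()
    rows: List[dict] = []
    curves: List[Optional[PassageCurve]] = []
    h = spec.template.capillary.length
    try:
        version = metadata.version("dermadiff")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    logger.info("sweep start: seed=%d version=%s grid=%dx%d n=%d",
                spec.seed, version, len(spec.diameters), len(spec.viscosities),
                spec.template.n_particles)
    cell = 0
    for d_p in spec.diameters:
        for eta in spec.viscosities:
            particle = ParticleSpec(d_p=d_p, rho_p=spec.template.particle.rho_p)
            fluid = replace(spec.template.fluid, eta=eta)
            row = {"d_p_nm": d_p * 1e9, "eta_mPas": eta * 1e3}
            if spec.template.capillary.r_h - d_p / 2.0 <= 0:
                logger.warning("cell d_p=%.3g eta=%.3g skipped: particle larger than capillary", d_p, eta)
                rows.append({**row, "D_eff_m2_per_s": np.nan, "n": np.nan,
                             "r_squared": np.nan, "skipped": True,
                             "reason": "particle larger than capillary"})
                curves.append(None)
                cell += 1
                continue
            cfg = replace(spec.template, particle=particle, fluid=fluid,
                          seed=spec.seed + cell)
            if spec.t_end_factor is not None:
                mfpt = mean_first_passage_time(
                    cfg.diffusivity, cfg.capillary.length, cfg.release_offset
                )
                cfg = replace(cfg, t_end=spec.t_end_factor * mfpt)
            curve = run_simulation(cfg)
            fit = fit_hill(curve, h)
            logger.info(
                "cell d_p=%.3gnm eta=%.3gmPas seed=%d: D_eff=%.3e n=%.3f R2=%.4f",
                d_p * 1e9, eta * 1e3, cfg.seed, fit.D_eff, fit.n, fit.r_squared,
            )
            rows.append({**row, "D_eff_m2_per_s": fit.D_eff, "n": fit.n,
                         "r_squared": fit.r_squared, "skipped": False, "reason": ""})
            curves.append(curve)
            cell += 1
    table = pd.DataFrame(rows)
    if spec.output_dir is not None:
        out = Path(spec.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "deff_table.csv", index=False)
        for row, curve in zip(rows, curves):
            if curve is None:
                continue
            name = f"curve_dp{row['d_p_nm']:g}nm_eta{row['eta_mPas']:g}mPas.csv"
            curve.to_csv(out / name)
    logger.info("sweep done in %.1f s", time.monotonic() - t0)
    return table


def build_comparison(table: pd.DataFrame, T: float = COMPARISON_TEMPERATURE) -> pd.DataFrame:
    """Free (diameter-form Stokes-Einstein) vs effective diffusivity per row.

    Adds ``D_m2_per_s`` = k_B*T/(6*pi*eta*d_p) evaluated at temperature
    ``T`` and ``ratio`` = D / D_eff.  The default temperature is the one at
    which the published comparison is numerically consistent (293 K), which
    differs from the 298 K quoted alongside it; the discrepancy is logged.
    """
    if T != 298.0:
        logger.info("comparison computed at T=%.1f K (published column is "
                    "consistent with this value, not the quoted 298 K)", T)
    rows = table[~table.get("skipped", pd.Series(False, index=table.index)).astype(bool)]
    if (rows["D_eff_m2_per_s"] <= 0).any():
        raise ValueError("all D_eff values must be positive")
    out = rows.copy()
    d = np.array([
        stokes_einstein_printed(
            ParticleSpec(d_p=r.d_p_nm * 1e-9, rho_p=2200.0),
            Fluid(eta=r.eta_mPas * 1e-3, T=T),
        )
        for r in rows.itertuples()
    ])
    out["D_m2_per_s"] = d
    out["ratio"] = out["D_m2_per_s"] / out["D_eff_m2_per_s"]
    return out


_ALLOWED_KEYS = {
    "diameters_nm", "diameters_m", "viscosities_mPas", "viscosities_Pas",
    "n_particles", "t_end_s", "t_end_factor", "seed", "scheme",
    "release_offset_m", "temperature_K", "fluid_density_kg_m3",
    "particle_density_kg_m3", "geometry", "capillary_length_m", "output_dir",
}
_ALLOWED_GEOMETRY_KEYS = {"L1_m", "L2_m", "a_m", "b_m", "d1_m", "d2_m", "h_k_m"}


def load_config(path: Union[str, Path]) -> SweepSpec:
    """Parse a declarative YAML sweep configuration into a SweepSpec.

    Units are explicit in key names (``viscosities_mPas`` vs
    ``viscosities_Pas``, ``diameters_nm`` vs ``diameters_m``).  Unknown keys
    and ambiguous duplicates raise a validation error listing the offending
    keys.  The resolved configuration is echoed to the run log.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = sorted(set(raw) - _ALLOWED_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "diameters_nm" in raw and "diameters_m" in raw:
        raise ValueError("ambiguous: both diameters_nm and diameters_m given")
    if "viscosities_mPas" in raw and "viscosities_Pas" in raw:
        raise ValueError("ambiguous: both viscosities_mPas and viscosities_Pas given")

    if "diameters_nm" in raw:
        diameters = [float(x) * 1e-9 for x in raw["diameters_nm"]]
    elif "diameters_m" in raw:
        diameters = [float(x) for x in raw["diameters_m"]]
    else:
        raise ValueError("missing diameters (diameters_nm or diameters_m)")
    if "viscosities_mPas" in raw:
        viscosities = [float(x) * 1e-3 for x in raw["viscosities_mPas"]]
    elif "viscosities_Pas" in raw:
        viscosities = [float(x) for x in raw["viscosities_Pas"]]
    else:
        raise ValueError("missing viscosities (viscosities_mPas or viscosities_Pas)")
    if any(d <= 0 for d in diameters):
        raise ValueError("diameters must be positive")
    if any(v <= 0 for v in viscosities):
        raise ValueError("viscosities must be positive")

    geo_raw = raw.get("geometry", {})
    geo_unknown = sorted(set(geo_raw) - _ALLOWED_GEOMETRY_KEYS)
    if geo_unknown:
        raise ValueError(f"unknown geometry keys: {geo_unknown}")
    ref = REFERENCE_GEOMETRY
    geom = BrickMortarGeometry(
        L1=float(geo_raw.get("L1_m", ref["L"])),
        L2=float(geo_raw.get("L2_m", ref["L"])),
        a=float(geo_raw.get("a_m", ref["a"])),
        b=float(geo_raw.get("b_m", ref["a"])),
        d1=float(geo_raw.get("d1_m", ref["d"])),
        d2=float(geo_raw.get("d2_m", ref["d"])),
        h_k=float(geo_raw.get("h_k_m", ref["h_k"])),
    )
    cap = build_capillary(geom, float(raw.get("capillary_length_m", REFERENCE_CAPILLARY_LENGTH)))
    template = SimulationConfig(
        capillary=cap,
        particle=ParticleSpec(d_p=diameters[0], rho_p=float(raw.get("particle_density_kg_m3", 2200.0))),
        fluid=Fluid(
            eta=viscosities[0],
            rho_f=float(raw.get("fluid_density_kg_m3", 1000.0)),
            T=float(raw.get("temperature_K", 298.0)),
        ),
        n_particles=int(raw.get("n_particles", 1000)),
        t_end=float(raw.get("t_end_s", 500.0)),
        release_offset=float(raw.get("release_offset_m", 3e-8)),
        seed=int(raw.get("seed", 0)),
        scheme=str(raw.get("scheme", "overdamped")),
    )
    spec = SweepSpec(
        diameters=diameters,
        viscosities=viscosities,
        template=template,
        output_dir=Path(raw["output_dir"]) if "output_dir" in raw else None,
        seed=int(raw.get("seed", 0)),
        t_end_factor=(float(raw["t_end_factor"]) if raw.get("t_end_factor") is not None
                      else (None if "t_end_s" in raw else 20.0)),
    )
    logger.info("loaded config %s: %s", path, dump_config(spec))
    return spec


def dump_config(spec: SweepSpec) -> str:
    """Serialise a SweepSpec back to the YAML schema of :func:`load_config`."""
    cap = spec.template.capillary
    data = {
        "diameters_nm": [d * 1e9 for d in spec.diameters],
        "viscosities_mPas": [v * 1e3 for v in spec.viscosities],
        "n_particles": spec.template.n_particles,
        "seed": spec.seed,
        "scheme": spec.template.scheme,
        "release_offset_m": spec.template.release_offset,
        "temperature_K": spec.template.fluid.T,
        "fluid_density_kg_m3": spec.template.fluid.rho_f,
        "particle_density_kg_m3": spec.template.particle.rho_p,
        "capillary_length_m": cap.length,
    }
    if spec.t_end_factor is not None:
        data["t_end_factor"] = spec.t_end_factor
    else:
        data["t_end_s"] = spec.template.t_end
    if spec.output_dir is not None:
        data["output_dir"] = str(spec.output_dir)
    return yaml.safe_dump(data, sort_keys=False)


def packaged_default_config() -> Path:
    """Path of the packaged reference sweep configuration."""
    return Path(str(resources.files("dermadiff") / "configs" / "default_sweep.yaml"))


def plot_passage_curves(
    curves: Sequence[PassageCurve],
    labels: Sequence[str],
    out: Union[str, Path],
    title: str = "",
) -> None:
    """Plot passage fraction against normalized time for a set of curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve, label in zip(curves, labels):
        ax.plot(curve.normalized_times, curve.fraction, label=label)
    ax.set_xlabel("normalized time t / t_c")
    ax.set_ylabel("passage fraction N_pt / N_p0")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
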