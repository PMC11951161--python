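"""Reproduction drivers: time-step scans, HMR comparison, charging scan.

These orchestrate the engine at desk scale: a shared melt/equilibration at
dt = 0.5 fs from the lattice start (the per-dt runs all launch from the
same equilibrated configuration, mirroring the bulk-water protocol), then
per-dt, per-seed equilibration and production, with every reported
uncertainty produced by the Friedberg-Cameron path and all parameters
recorded in a reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import AVOGADRO, KB
from .dynamics import ConstraintError, IntegratorSpec
from .ensembles import EnsembleSpec, run_md
from .estimators import compressibility, com_corrected_t_trans, friedberg_cameron
from .free_energy import charging_potential
from .interactions import InteractionSpec
from .models import (
    RNGStream,
    build_water_lattice,
    init_velocities,
    repartition_hydrogen_mass,
    water_model,
)
from .synthetic import gen_toy_ion_box

logger = logging.getLogger(__name__)

__all__ = ["ScanReport", "load_config", "timestep_scan", "hmr_comparison", "charging_scan"]

#: Desk-scale defaults; a config file overrides any subset of these.
DEFAULTS: dict = {
    "model": "spce",
    "n_waters": 125,
    "density": 0.997,
    "dt_list": [0.5, 3.0],
    "seeds": [1, 2, 3],
    "ensemble": "nvt",  # nvt | npt
    "thermostat": "csvr",
    "T_set": 298.15,
    "tau_csvr": 500.0,
    "gamma_langevin": 1.0,
    "p_set": 1.0,
    "mc_every": 25,
    "rcut": 7.0,
    "ewald_tol": 1.0e-5,
    "pre_equil_steps": 10000,  # shared melt at dt = 0.5 fs
    "n_equil_steps": 4000,  # per-dt equilibration (discarded)
    "n_steps": 12000,  # per-dt production
    "log_every": 10,
    "hmr_m_H": None,  # e.g. 3.024
    "tagged_molecule": None,
    "binding_every": None,
    # charging-scan extras
    "charge_states": [2.0, 3.0],
    "ion_sigma": 2.584,
    "ion_eps": 0.1,
    "sample_every": 25,
}


@dataclass
class ScanReport:
    """Per-(dt, seed) rows plus pooled per-dt summary and a manifest."""

    data: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(outdir / "scan_rows.csv", index=False)
        self.summary.to_csv(outdir / "scan_summary.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def load_config(source) -> dict:
    """Merge a YAML file / dict over the desk-scale defaults."""
    cfg = dict(DEFAULTS)
    if source is None:
        return cfg
    if isinstance(source, dict):
        cfg.update(source)
        return cfg
    with open(source) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def _interaction(cfg: dict) -> InteractionSpec:
    return InteractionSpec(
        rcut_lj=cfg["rcut"], rcut_real=cfg["rcut"],
        ewald_tol=cfg["ewald_tol"], tail_correction=True,
    )


def _ensemble(cfg: dict, barostat: bool, dlnv: float | None = None) -> EnsembleSpec:
    return EnsembleSpec(
        thermostat=cfg["thermostat"],
        T_set=cfg["T_set"],
        tau_csvr=cfg["tau_csvr"],
        gamma_langevin=cfg["gamma_langevin"],
        barostat="mc" if barostat else "none",
        p_set=cfg["p_set"],
        mc_every=cfg["mc_every"],
        mc_dlnV_max=dlnv if dlnv is not None else 0.02,
    )


def prepare_equilibrated_box(cfg: dict, seed: int):
    """Lattice start, Maxwell-Boltzmann velocities, dt = 0.5 fs NVT melt."""
    model = water_model(cfg["model"])
    if cfg["hmr_m_H"]:
        model = repartition_hydrogen_mass(model, float(cfg["hmr_m_H"]))
    ispec = _interaction(cfg)
    config = build_water_lattice(model, cfg["n_waters"], cfg["density"], RNGStream(seed))
    config = init_velocities(config, cfg["T_set"], RNGStream(seed))
    melt = EnsembleSpec(thermostat="csvr", T_set=cfg["T_set"], tau_csvr=100.0)
    run_md(
        config, IntegratorSpec(dt=0.5), melt, cfg["pre_equil_steps"],
        log_every=max(cfg["pre_equil_steps"] // 10, 1),
        rng=RNGStream(seed + 7919), interaction=ispec,
    )
    return config, model, ispec


def _run_one(cfg, start, ispec, dt, seed, barostat):
    """Per-dt equilibration + production; returns the production log."""
    config = start.copy()
    integ = IntegratorSpec(dt=dt)
    if barostat:
        ens_eq = _ensemble(cfg, True)
        log_eq = run_md(
            config, integ, ens_eq, cfg["n_equil_steps"],
            log_every=max(cfg["n_equil_steps"] // 10, 1),
            rng=RNGStream(seed * 13 + 1), interaction=ispec,
            tune_barostat_until=cfg["n_equil_steps"] // 2,
        )
        ens = _ensemble(cfg, True, dlnv=log_eq.meta["mc_dlnV_max_final"])
    else:
        ens = _ensemble(cfg, False)
        run_md(
            config, integ, ens, cfg["n_equil_steps"],
            log_every=max(cfg["n_equil_steps"] // 10, 1),
            rng=RNGStream(seed * 13 + 1), interaction=ispec,
        )
    return run_md(
        config, integ, ens, cfg["n_steps"], log_every=cfg["log_every"],
        rng=RNGStream(seed * 13 + 2), interaction=ispec,
        tagged_molecule=cfg["tagged_molecule"], binding_every=cfg["binding_every"],
    )


def timestep_scan(config_file=None) -> ScanReport:
    """Volume/temperature/binding-energy scan over the dt list.

    For every dt and seed: shared dt = 0.5 fs melt, per-dt equilibration,
    production, and per-run statistics (Friedberg-Cameron uncertainties;
    compressibility for NpT runs).  An unstable trajectory flags its row
    and the scan continues.
    """
    cfg = load_config(config_file)
    barostat = cfg["ensemble"] == "npt"
    model = water_model(cfg["model"])
    molar_mass = model.total_mass
    rows = []
    for seed in cfg["seeds"]:
        start, model, ispec = prepare_equilibrated_box(cfg, seed)
        for dt in cfg["dt_list"]:
            row = {"dt_fs": dt, "seed": seed, "stable": True}
            try:
                log = _run_one(cfg, start, ispec, dt, seed, barostat)
                d = log.data
                if not np.isfinite(d.e_potential.values).all():
                    raise FloatingPointError("non-finite potential energy")
                v = friedberg_cameron(d.volume_A3.values)
                tt = friedberg_cameron(d.T_trans_K.values)
                tr = friedberg_cameron(d.T_rot_K.values)
                row.update(
                    V_mean_A3=v.mean, V_stderr_A3=v.stderr,
                    v_per_mol_A3=v.mean / cfg["n_waters"],
                    density_kg_m3=cfg["n_waters"] * molar_mass
                    / (AVOGADRO * v.mean * 1e-24) * 1e3,
                    T_trans_K=tt.mean, T_trans_stderr_K=tt.stderr,
                    T_rot_K=tr.mean, T_rot_stderr_K=tr.stderr,
                    T_gap_K=tt.mean - tr.mean,
                    T_gap_corrected_K=com_corrected_t_trans(
                        tt.mean, cfg["n_waters"]
                    ) - tr.mean,
                )
                if barostat:
                    kap = compressibility(d.volume_A3.values, cfg["T_set"])
                    row.update(
                        kappa_T_per_bar=kap.value,
                        kappa_T_stderr=kap.uncertainty,
                    )
                if "binding_kcal" in d:
                    b = friedberg_cameron(d.binding_kcal.dropna().values)
                    row.update(binding_kcal=b.mean, binding_stderr_kcal=b.stderr)
            except (ConstraintError, FloatingPointError, ValueError) as exc:
                logger.warning("dt=%s seed=%s unstable: %s", dt, seed, exc)
                row["stable"] = False
            rows.append(row)
    data = pd.DataFrame(rows).sort_values(["dt_fs", "seed"]).reset_index(drop=True)
    summary = _summarize(data)
    manifest = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        "seeds": list(cfg["seeds"]),
        "m_H_amu": model.m_H,
        "m_O_amu": model.m_O,
    }
    return ScanReport(data=data, summary=summary, manifest=manifest)


def _summarize(data: pd.DataFrame) -> pd.DataFrame:
    """Pool seeds per dt: means and seed-scatter standard errors."""
    out = []
    for dt, grp in data[data.stable].groupby("dt_fs"):
        row = {"dt_fs": dt, "n_seeds": len(grp)}
        for col in grp.columns:
            if col in ("dt_fs", "seed", "stable") or not np.issubdtype(
                grp[col].dtype, np.number
            ):
                continue
            row[col] = grp[col].mean()
            if len(grp) > 1:
                row[col + "_seed_sem"] = grp[col].std(ddof=1) / np.sqrt(len(grp))
        out.append(row)
    return pd.DataFrame(out).sort_values("dt_fs").reset_index(drop=True)


def hmr_comparison(config_file=None) -> ScanReport:
    """Paired scan with and without hydrogen-mass repartitioning.

    Matched dt values and seeds; the repartitioned runs use m_H = 3.024 amu
    (oxygen reduced to keep 18.0154 amu total) unless the config overrides
    ``hmr_m_H``.
    """
    cfg = load_config(config_file)
    m_h = cfg["hmr_m_H"] or 3.024
    plain = timestep_scan({**cfg, "hmr_m_H": None})
    repart = timestep_scan({**cfg, "hmr_m_H": m_h})
    plain.data["hmr"] = False
    repart.data["hmr"] = True
    plain.summary["hmr"] = False
    repart.summary["hmr"] = True
    data = pd.concat([plain.data, repart.data], ignore_index=True)
    summary = pd.concat([plain.summary, repart.summary], ignore_index=True)
    manifest = {
        "plain": plain.manifest,
        "hmr": repart.manifest,
        "m_H_amu_hmr": m_h,
    }
    return ScanReport(data=data, summary=summary, manifest=manifest)


def charging_scan(config_file=None) -> pd.DataFrame:
    """Linear-response charging free energy of a toy LJ ion vs dt.

    For each dt and charge state q, the ion carries charge q/2 (the
    lambda = 0.5 ensemble); the sampled TI integrand phi gives the
    linear-response mu_elec = <phi>_{0.5}.  Reported per (dt, q):
    mu_elec with stderr, and beta*Delta mu/q^2 relative to the smallest dt.
    q = 0 rows short-circuit to mu_elec = 0.
    """
    cfg = load_config(config_file)
    beta = 1.0 / (KB * cfg["T_set"])
    ispec = _interaction(cfg)
    rows = []
    for q in cfg["charge_states"]:
        for dt in cfg["dt_list"]:
            for seed in cfg["seeds"]:
                if q == 0.0:
                    rows.append(
                        {"dt_fs": dt, "q_e": 0.0, "seed": seed,
                         "mu_elec_kcal": 0.0, "mu_stderr_kcal": 0.0}
                    )
                    continue
                lam = 0.5
                config = gen_toy_ion_box(
                    cfg["n_waters"], water_model(cfg["model"]),
                    {"charge": lam * q, "sigma": cfg["ion_sigma"],
                     "eps": cfg["ion_eps"]},
                    seed=seed, density=cfg["density"], interaction=ispec,
                )
                config = init_velocities(config, cfg["T_set"], RNGStream(seed))
                ens = _ensemble(cfg, False)
                ion_site = config.n_sites - 1
                run_md(
                    config, IntegratorSpec(dt=0.5), ens, cfg["pre_equil_steps"],
                    log_every=max(cfg["pre_equil_steps"] // 10, 1),
                    rng=RNGStream(seed + 31), interaction=ispec,
                )
                run_md(
                    config, IntegratorSpec(dt=dt), ens, cfg["n_equil_steps"],
                    log_every=max(cfg["n_equil_steps"] // 10, 1),
                    rng=RNGStream(seed + 37), interaction=ispec,
                )

                def phi_cb(istep, c, _site=ion_site, _lam=lam):
                    return {"phi_kcal": charging_potential(c, _site, ispec, _lam)}

                log = run_md(
                    config, IntegratorSpec(dt=dt), ens, cfg["n_steps"],
                    log_every=cfg["sample_every"],
                    rng=RNGStream(seed + 41), interaction=ispec, callback=phi_cb,
                )
                est = friedberg_cameron(log.data.phi_kcal.values)
                rows.append(
                    {"dt_fs": dt, "q_e": q, "seed": seed,
                     "mu_elec_kcal": est.mean, "mu_stderr_kcal": est.stderr}
                )
    df = pd.DataFrame(rows)

    # pool seeds (combining seed scatter with the propagated per-run
    # Friedberg-Cameron errors) and reference each charge state to its
    # smallest dt
    def _pool(grp):
        n = len(grp)
        scatter = grp.mu_elec_kcal.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        propagated = np.sqrt((grp.mu_stderr_kcal**2).mean() / n)
        return pd.Series(
            {
                "mu_elec_kcal": grp.mu_elec_kcal.mean(),
                "mu_stderr_kcal": max(scatter, propagated),
            }
        )

    pooled = (
        df.groupby(["q_e", "dt_fs"])[["mu_elec_kcal", "mu_stderr_kcal"]]
        .apply(_pool)
        .reset_index()
    )
    out = []
    for q, grp in pooled.groupby("q_e"):
        grp = grp.sort_values("dt_fs")
        ref = grp.iloc[0]
        for _, r in grp.iterrows():
            d = dict(r)
            if q != 0.0:
                d["beta_dmu_per_q2"] = beta * (r.mu_elec_kcal - ref.mu_elec_kcal) / q**2
            else:
                d["beta_dmu_per_q2"] = 0.0
            out.append(d)
    return pd.DataFrame(out)
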