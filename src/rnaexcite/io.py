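"""Delimited-text I/O and reproducible pipeline runs.

All interchange is plain TSV; configs and results are YAML.  Schemas:

R1rho table (one row per delay point, or per setting for pre-fit data):
    construct  residue  nucleus  field_h1_MHz  temperature_K  sl_power_Hz
    offset_Hz  delay_s  intensity  intensity_err
    -- or instead of the last three --  r1rho_s1  r1rho_err

CEST table (one row per carrier):
    construct  residue  nucleus  field_h1_MHz  gs_ppm  component
    b1_Hz  mixing_time_s  carrier_ppm  intensity  reference_intensity

Rate table (one row per temperature and direction):
    construct  direction  temperature_C  k_s1  k_err
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import celsius_to_kelvin, larmor_mhz
from .exchange import CESTSetting, SpinLockSetting, SpinProbe
from .fitting import FitResult, fit_cest, fit_r1rho_global, mc_errors
from .profiles import CESTProfile, R1rhoProfile
from .synth import gen_cest_dataset, gen_r1rho_dataset, t1_ground_truth
from .thermo import RateSeries, vant_hoff_fit

__all__ = [
    "read_r1rho_table",
    "write_r1rho_table",
    "read_cest_table",
    "write_cest_table",
    "read_rate_table",
    "write_rate_table",
    "write_fit_report",
    "RunConfig",
    "run_pipeline",
]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() & df[c].notna()].tolist()
        if bad:
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path}: non-numeric values in column {c!r} at line(s) "
                f"{[i + 2 for i in bad[:5]]}"
            )
        df[c] = vals


def read_r1rho_table(path) -> list:
    """Parse an R1rho TSV into per-(construct, residue) profiles."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    base = ["construct", "residue", "nucleus", "field_h1_MHz", "temperature_K",
            "sl_power_Hz", "offset_Hz"]
    _require_columns(df, base, path)
    prefit = "r1rho_s1" in df.columns
    if prefit:
        _require_columns(df, ["r1rho_s1", "r1rho_err"], path)
        numeric = ["field_h1_MHz", "temperature_K", "sl_power_Hz", "offset_Hz",
                   "r1rho_s1", "r1rho_err"]
    else:
        _require_columns(df, ["delay_s", "intensity", "intensity_err"], path)
        numeric = ["field_h1_MHz", "temperature_K", "sl_power_Hz", "offset_Hz",
                   "delay_s", "intensity", "intensity_err"]
    _check_numeric(df, numeric, path)

    profiles = []
    for (construct, residue), g in df.groupby(["construct", "residue"], sort=True):
        nuc = str(g["nucleus"].iloc[0])
        probe = SpinProbe(
            residue_id=int(residue),
            nucleus=nuc,
            larmor_MHz=larmor_mhz(float(g["field_h1_MHz"].iloc[0]), nuc),
        )
        settings, delays, intens, errs, r1rho, r1rho_err = [], [], [], [], [], []
        for (p, o), gg in g.groupby(["sl_power_Hz", "offset_Hz"], sort=True):
            settings.append(SpinLockSetting.from_hz(float(p), float(o)))
            if prefit:
                r1rho.append(float(gg["r1rho_s1"].iloc[0]))
                r1rho_err.append(float(gg["r1rho_err"].iloc[0]))
            else:
                delays.append(gg["delay_s"].to_numpy())
                intens.append(gg["intensity"].to_numpy())
                errs.append(gg["intensity_err"].to_numpy())
        profiles.append(
            R1rhoProfile(
                probe=probe,
                settings=settings,
                delays=delays or None,
                intensities=intens or None,
                errors=errs or None,
                r1rho=np.array(r1rho) if prefit else None,
                r1rho_err=np.array(r1rho_err) if prefit else None,
                construct=str(construct),
            )
        )
    return profiles


def write_r1rho_table(profiles, path, field_h1_MHz: float = 600.0,
                      temperature_K: float = 283.15) -> None:
    rows = []
    for prof in profiles:
        for i, s in enumerate(prof.settings):
            common = {
                "construct": prof.construct or "NA",
                "residue": prof.probe.residue_id,
                "nucleus": prof.probe.nucleus,
                "field_h1_MHz": field_h1_MHz,
                "temperature_K": temperature_K,
                "sl_power_Hz": s.power_Hz,
                "offset_Hz": s.offset_Hz,
            }
            if prof.has_intensities:
                for d, y, e in zip(prof.delays[i], prof.intensities[i], prof.errors[i]):
                    rows.append({**common, "delay_s": d, "intensity": y,
                                 "intensity_err": e})
            else:
                rows.append({**common, "r1rho_s1": prof.r1rho[i],
                             "r1rho_err": prof.r1rho_err[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cest_table(path) -> list:
    """Parse a CEST TSV into normalised per-(construct, residue, component)
    profiles."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    req = ["construct", "residue", "nucleus", "field_h1_MHz", "gs_ppm", "component",
           "b1_Hz", "mixing_time_s", "carrier_ppm", "intensity",
           "reference_intensity"]
    _require_columns(df, req, path)
    _check_numeric(df, ["field_h1_MHz", "gs_ppm", "b1_Hz", "mixing_time_s",
                        "carrier_ppm", "intensity", "reference_intensity"], path)
    out = []
    for (construct, residue, comp), g in df.groupby(
        ["construct", "residue", "component"], sort=True
    ):
        g = g.sort_values("carrier_ppm")
        nuc = str(g["nucleus"].iloc[0])
        probe = SpinProbe.from_ppm(
            residue_id=int(residue),
            nucleus=nuc,
            larmor_MHz=larmor_mhz(float(g["field_h1_MHz"].iloc[0]), nuc),
            gs_ppm=float(g["gs_ppm"].iloc[0]),
        )
        setting = CESTSetting(
            b1_Hz=float(g["b1_Hz"].iloc[0]),
            mixing_time=float(g["mixing_time_s"].iloc[0]),
            carrier_grid=tuple(g["carrier_ppm"].tolist()),
        )
        out.append(
            CESTProfile(
                probe=probe,
                setting=setting,
                component=str(comp),
                intensity=g["intensity"].to_numpy(),
                reference_intensity=float(g["reference_intensity"].iloc[0]),
                construct=str(construct),
            )
        )
    return out


def write_cest_table(profiles, path, field_h1_MHz: float = 600.0) -> None:
    rows = []
    for prof in profiles:
        for c, y in zip(prof.setting.grid, prof.intensity):
            rows.append({
                "construct": prof.construct or "NA",
                "residue": prof.probe.residue_id,
                "nucleus": prof.probe.nucleus,
                "field_h1_MHz": field_h1_MHz,
                "gs_ppm": prof.probe.gs_ppm,
                "component": prof.component,
                "b1_Hz": prof.setting.b1_Hz,
                "mixing_time_s": prof.setting.mixing_time,
                "carrier_ppm": c,
                "intensity": y,
                "reference_intensity": prof.reference_intensity,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rate_table(path) -> dict:
    """Parse a rate TSV into per-construct :class:`RateSeries` (Celsius
    temperatures converted to Kelvin)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["construct", "direction", "temperature_C", "k_s1"], path)
    _check_numeric(df, ["temperature_C", "k_s1"], path)
    has_err = "k_err" in df.columns
    if has_err:
        df["k_err"] = pd.to_numeric(df["k_err"], errors="coerce")
        if df["k_err"].isna().all():
            has_err = False
    out = {}
    for construct, g in df.groupby("construct", sort=True):
        fwd = g[g["direction"] == "fwd"].sort_values("temperature_C")
        bwd = g[g["direction"] == "bwd"].sort_values("temperature_C")
        if len(fwd) != len(bwd) or not np.allclose(
            fwd["temperature_C"].to_numpy(), bwd["temperature_C"].to_numpy()
        ):
            raise ValueError(
                f"{path}: construct {construct!r} needs matching fwd/bwd "
                "temperature grids"
            )
        out[str(construct)] = RateSeries(
            temperatures=celsius_to_kelvin(fwd["temperature_C"].to_numpy()),
            k1_values=fwd["k_s1"].to_numpy(),
            kminus1_values=bwd["k_s1"].to_numpy(),
            k1_errors=fwd["k_err"].to_numpy() if has_err else None,
            kminus1_errors=bwd["k_err"].to_numpy() if has_err else None,
            construct=str(construct),
        )
    return out


def write_rate_table(series_by_construct: dict, path) -> None:
    rows = []
    for construct, s in series_by_construct.items():
        for direction, k, e in (
            ("fwd", s.k1_values, s.k1_errors),
            ("bwd", s.kminus1_values, s.kminus1_errors),
        ):
            for i, T in enumerate(s.temperatures):
                rows.append({
                    "construct": construct,
                    "direction": direction,
                    "temperature_C": T - 273.15,
                    "k_s1": k[i],
                    "k_err": e[i] if e is not None else "",
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fit_report(fit: FitResult, prefix) -> None:
    """Write a dispersion-fit report: per-probe TSV plus a structured
    YAML results file with parameters, SDs and chi2/dof."""
    prefix = Path(prefix)
    rows = []
    for rid, pf in sorted(fit.probe_fits.items()):
        err = (fit.errors or {}).get("probes", {}).get(rid, {})
        rows.append({
            "residue": rid,
            "delta_omega_ppm": pf.delta_omega_ppm,
            "delta_omega_ppm_sd": err.get("delta_omega_ppm", ""),
            "R1_s1": pf.R1,
            "R2_s1": pf.R2,
        })
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    doc = {
        "pES": fit.params.pES,
        "pES_sd": (fit.errors or {}).get("pES"),
        "kex_s1": fit.params.kex,
        "kex_sd": (fit.errors or {}).get("kex"),
        "k1_s1": fit.params.k1,
        "kminus1_s1": fit.params.kminus1,
        "tau_ES_ms": 1e3 * fit.params.tau_ES,
        "chi2": fit.chi2,
        "dof": fit.dof,
        "flags": list(fit.flags),
        "version": __version__,
    }
    prefix.with_suffix(".yaml").write_text(yaml.safe_dump(doc, sort_keys=True))


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

KNOWN_STAGES = ("simulate", "fit-r1rho", "fit-cest", "vanthoff")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run; fully serialised
    into the results bundle for provenance."""

    outdir: str
    stages: tuple = KNOWN_STAGES
    seed: int = 7
    mc_iterations: int = 50
    global_fit: bool = True
    pES_truth: float = 0.062
    kex_truth: float = 453.0
    noise: float = 0.02
    r1rho_input: str | None = None
    cest_input: str | None = None
    rates_input: str | None = None

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(
                f"unknown stage(s) {unknown}; known stages: {list(KNOWN_STAGES)}"
            )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write a results bundle.

    Stage failures abort downstream stages; partial results stay on disk.
    Reruns with the same config and seed are bit-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    profiles = None
    cest_pairs = None
    truth = None
    fit = None

    for stage in config.stages:
        if stage == "simulate":
            truth = t1_ground_truth(
                pES=config.pES_truth, kex=config.kex_truth,
                noise=config.noise, seed=config.seed,
            )
            profiles, truth = gen_r1rho_dataset(truth, seed=config.seed)
            cest_pairs, _ = gen_cest_dataset(truth, seed=config.seed + 1)
            write_r1rho_table(profiles, outdir / "r1rho.tsv")
            write_cest_table(
                [p for pair in cest_pairs for p in pair], outdir / "cest.tsv"
            )
            (outdir / "truth.json").write_text(truth.to_json())
            results["stages"]["simulate"] = {"n_probes": len(profiles)}
        elif stage == "fit-r1rho":
            if profiles is None:
                if config.r1rho_input is None:
                    raise ValueError("fit-r1rho needs simulated data or r1rho_input")
                profiles = read_r1rho_table(config.r1rho_input)
            fit = fit_r1rho_global(profiles, seed=config.seed)
            fit.errors = mc_errors(
                fit, profiles, n_mc=config.mc_iterations, seed=config.seed
            )
            write_fit_report(fit, outdir / "fit_r1rho")
            results["stages"]["fit-r1rho"] = {
                "pES": fit.params.pES,
                "kex_s1": fit.params.kex,
                "tau_ES_ms": 1e3 * fit.params.tau_ES,
                "chi2_reduced": fit.chi2_reduced,
            }
        elif stage == "fit-cest":
            if cest_pairs is None and config.cest_input is not None:
                profs = read_cest_table(config.cest_input)
                alphas = [p for p in profs if p.component == "alpha"]
            elif cest_pairs is not None:
                alphas = [a for a, _ in cest_pairs]
            else:
                raise ValueError("fit-cest needs simulated data or cest_input")
            if fit is None:
                raise ValueError("fit-cest requires a prior fit-r1rho stage")
            shifts = {}
            for prof in alphas:
                r = fit_cest(prof, fit.params)
                shifts[prof.probe.residue_id] = {
                    "es_shift_ppm": r.es_shift_ppm,
                    "sd_ppm": r.es_shift_sd,
                }
            results["stages"]["fit-cest"] = shifts
        elif stage == "vanthoff":
            if config.rates_input is None:
                results["stages"]["vanthoff"] = {"skipped": "no rates_input"}
                continue
            series = read_rate_table(config.rates_input)
            results["stages"]["vanthoff"] = {
                name: dataclasses.asdict(vant_hoff_fit(s))
                for name, s in series.items()
            }
    (outdir / "results.yaml").write_text(
        yaml.safe_dump(results, sort_keys=True, default_flow_style=False)
    )
    return results
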