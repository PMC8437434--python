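"""Config-driven orchestration of the full analysis.

``run_analysis`` executes the enabled stages in dependency order —
trace preparation → baseline global fit → seeded fit → chaperone fits and
hypothesis comparison, with seed sizing and binding analysis running
independently — and writes a single provenance-stamped JSON report plus
per-stage intermediates.  ``demo_bundle`` emits a complete synthetic
dataset and a ready-to-run config for it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import binding as bd
from . import hydrodynamics as hyd
from . import synthetic as syn
from . import traces as tp
from .datasets import KineticDataset
from .exceptions import DependencyError, InvalidInputError, NotSaturatedError
from .fitting import (
    ChaperoneRateModel,
    FitSettings,
    SeededGlobalModel,
    UnseededGlobalModel,
    compare_rate_hypotheses,
)

__all__ = ["AnalysisConfig", "run_analysis", "demo_bundle"]

logger = logging.getLogger(__name__)

_STAGES = ("prep", "baseline_fit", "seeded_fit", "chaperone_fit",
           "seed_sizing", "binding")


class AnalysisConfig:
    """Validated analysis configuration loaded from YAML or a dict."""

    def __init__(self, data: dict, base_dir: Path | str = "."):
        self.data = data
        self.base_dir = Path(base_dir)
        self.out_dir = Path(data.get("out_dir", "taukinetics_out"))
        if not self.out_dir.is_absolute():
            self.out_dir = self.base_dir / self.out_dir
        stages = data.get("stages", {})
        unknown = set(stages) - set(_STAGES)
        if unknown:
            raise InvalidInputError(f"unknown stages: {sorted(unknown)}")
        self.stages = {s: bool(stages.get(s, False)) for s in _STAGES}
        self.inputs = data.get("inputs", {})
        fit = data.get("fit", {})
        self.settings = FitSettings(
            max_iterations=int(fit.get("max_iterations", 60)),
            popsize=int(fit.get("popsize", 12)),
            tolerance=float(fit.get("tolerance", 1e-3)),
            rng_seed=int(fit.get("rng_seed", 0)),
            grid_points=int(fit.get("grid_points", 25)),
        )
        prep = data.get("prep", {})
        self.bin_size = int(prep.get("bin_size", 1))
        self.plateau_fraction = float(prep.get("plateau_fraction", 0.1))
        seed = data.get("seed", {})
        self.seed_length = float(seed.get("L", 100.0))
        self.b_nm = float(seed.get("b_nm", 10.0))
        self.spacing_nm = float(seed.get("spacing_nm",
                                         hyd.DEFAULT_MONOMER_SPACING_NM))
        self.nc = int(data.get("nc", 2))
        inst = data.get("instrument")
        self.instrument = None
        if inst is not None:
            self.instrument = hyd.InstrumentParams(
                lambda0=float(inst["lambda0_m"]),
                theta=float(inst["theta_deg"]),
                n=float(inst.get("n", 1.334)),
                T=float(inst.get("T_K", hyd.DEFAULT_TEMPERATURE_K)),
                eta=float(inst.get("eta_Pa_s", hyd.DEFAULT_VISCOSITY_PA_S)),
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data, base_dir=path.parent)

    def path(self, key: str) -> Path | None:
        p = self.inputs.get(key)
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def require(self, key: str, stage: str) -> Path:
        p = self.path(key)
        if p is None or not p.exists():
            raise DependencyError(
                f"stage {stage!r} needs input {key!r} "
                f"({'missing from config' if p is None else f'not found: {p}'})"
            )
        return p

    def config_hash(self) -> str:
        # the output location is not analysis content
        data = {k: v for k, v in self.data.items() if k != "out_dir"}
        payload = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_analysis(config: AnalysisConfig) -> dict:
    """Run all enabled stages and return (and write) the run report."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "rng_seed": config.settings.rng_seed,
            "settings_hash": config.settings.settings_hash(),
            "software": "taukinetics",
        },
        "warnings": [],
        "stages": {},
    }

    mass_traces = None
    if config.stages["prep"]:
        raw_path = config.require("raw_traces_csv", "prep")
        raw = tp.read_trace_csv(raw_path, kind="raw")
        baseline_path = config.path("baseline_traces_csv")
        if baseline_path is not None and baseline_path.exists():
            baselines = {tr.condition.key(): tr
                         for tr in tp.read_trace_csv(baseline_path, kind="raw")}
            raw = [tp.subtract_baseline(tr, baselines[tr.condition.key()])
                   if tr.condition.key() in baselines else tr for tr in raw]
        if config.bin_size > 1:
            raw = [tp.bin_trace(tr, config.bin_size) for tr in raw]
        spec = tp.ConversionSpec.from_traces(
            [tr for tr in raw if not tr.condition.seeded],
            plateau_fraction=config.plateau_fraction)
        mass_traces = tp.signal_to_mass(raw, spec)
        tp.write_trace_csv(mass_traces, out / "mass_traces.csv", kind="mass")
        report["stages"]["prep"] = {
            "n_traces": len(mass_traces),
            "conversion": {"mmax_uM": spec.mmax, "Smax_inf_au": spec.Smax_inf},
            "output": "mass_traces.csv",
        }
    elif config.path("mass_traces_csv") is not None:
        mass_traces = tp.read_trace_csv(config.require("mass_traces_csv", "load"),
                                        kind="mass")

    dataset = KineticDataset(list(mass_traces)) if mass_traces else None

    # --- half-times and scaling on the chaperone-free unseeded series
    if dataset is not None and config.stages["prep"]:
        pairs, skipped = [], []
        base = dataset.filter(lambda c: not c.seeded and c.chaperone_conc == 0)
        for tr in base:
            try:
                ht = tp.extract_half_time(tr, config.plateau_fraction)
                pairs.append((tr.condition.m0, ht.t_half))
            except NotSaturatedError as exc:
                skipped.append(str(exc))
        if skipped:
            report["warnings"].extend(skipped)
        if len({m for m, _ in pairs}) >= 3:
            sc = tp.fit_scaling_exponent(pairs)
            report["stages"]["scaling"] = {
                "gamma": sc.gamma, "gamma_stderr": sc.gamma_stderr,
                "curvature_coeff": sc.curvature_coeff,
                "curvature_significant": sc.curvature_significant,
                "n_half_times": len(pairs),
            }

    reduced_res = None
    if config.stages["baseline_fit"]:
        if dataset is None:
            raise DependencyError("baseline_fit needs prepared mass traces "
                                  "(enable prep or provide mass_traces_csv)")
        base = dataset.filter(lambda c: not c.seeded and c.chaperone_conc == 0)
        reduced_res = UnseededGlobalModel(base, nc=config.nc).fit(config.settings)
        report["stages"]["baseline_fit"] = reduced_res.to_dict()
        (out / "baseline_fit.json").write_text(
            json.dumps(reduced_res.to_dict(), indent=2))

    seed_geometry = None
    if config.stages["seed_sizing"]:
        dls_path = config.require("dls_csv", "seed_sizing")
        if config.instrument is None:
            raise DependencyError("seed_sizing needs an 'instrument' section")
        import pandas as pd

        df = pd.read_csv(dls_path)
        curve = hyd.AutocorrelationCurve(df["lag_s"].to_numpy(float),
                                         df["g2"].to_numpy(float))
        diff, seed_geometry = hyd.size_seed(curve, config.instrument,
                                            b_nm=config.b_nm,
                                            spacing_nm=config.spacing_nm)
        hyd.report_json(diff, seed_geometry, out / "seed_sizing.json",
                        config.instrument)
        report["stages"]["seed_sizing"] = {
            "beta": diff.beta, "D_m2s": diff.D, **seed_geometry.to_dict()}

    seed_L = seed_geometry.L if seed_geometry is not None else config.seed_length

    absolute_res = None
    if config.stages["seeded_fit"]:
        if reduced_res is None:
            raise DependencyError("seeded_fit needs the baseline_fit stage")
        seeded = dataset.filter(lambda c: c.seeded and c.chaperone_conc == 0)
        absolute_res = SeededGlobalModel(seeded, reduced_res, L=seed_L).fit(
            config.settings)
        report["stages"]["seeded_fit"] = absolute_res.to_dict()
        (out / "seeded_fit.json").write_text(
            json.dumps(absolute_res.to_dict(), indent=2))

    if config.stages["chaperone_fit"]:
        if absolute_res is None:
            raise DependencyError("chaperone_fit needs the seeded_fit stage")
        chap_report = {}
        names = sorted({tr.condition.chaperone for tr in dataset
                        if tr.condition.chaperone})
        for name in names:
            sub = dataset.filter(lambda c, n=name: c.chaperone in (n, None))
            effects = []
            for hyp in ("kn", "kp"):
                unseeded = sub.filter(lambda c: not c.seeded)
                effects.append(ChaperoneRateModel(
                    unseeded, absolute_res.params, hyp, L=seed_L
                ).fit(config.settings))
            entry = {e.hypothesis: e.to_dict() for e in effects}
            entry["comparison"] = {
                "ranking": list(compare_rate_hypotheses(effects).ranking),
            }
            chap_report[name] = entry
        report["stages"]["chaperone_fit"] = chap_report
        (out / "chaperone_fit.json").write_text(json.dumps(chap_report, indent=2))

    if config.stages["binding"]:
        binding_report = {}
        titrations = config.inputs.get("titrations", {})
        for label, rel in titrations.items():
            p = Path(rel)
            p = p if p.is_absolute() else config.base_dir / p
            curve = bd.read_titration_csv(p)
            fit = bd.fit_one_site(curve)
            binding_report[label] = fit.to_dict()
        nmr_path = config.path("nmr_csv")
        if nmr_path is not None and nmr_path.exists():
            records = bd.read_peak_table(nmr_path)
            profile = bd.intensity_ratio_profile(records)
            csps = bd.compute_csp(records)
            sig = bd.flag_significant_csp(csps)
            binding_report["nmr"] = {
                "regions": [list(r) for r in profile.regions],
                "n_strong_attenuation": int(profile.strong_attenuation.sum()),
                "n_significant_csp": int(sum(sig.values())),
            }
            bd.profile_report(profile, out / "nmr_profile")
        report["stages"]["binding"] = binding_report

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def demo_bundle(seed: int = 0, out_dir="taukinetics_demo") -> Path:
    """Write a complete synthetic dataset plus a ready-to-run config.

    The bundle holds a raw ThT plate CSV (monomer series, an elongation-
    suppressing chaperone dose series, and chaperone-free seeded wells), a
    DLS autocorrelation curve of length-100 seeds, two anisotropy
    titrations, an NMR peak table with both amyloid-motif footprints, and
    ``config.yaml`` wiring them into :func:`run_analysis`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    def subseed():
        return int(rng.integers(0, 2**31 - 1))

    scenario = syn.ScenarioSpec(
        chaperone="HSPB1",
        chaperone_effects={0.0: (1, 1, 1), 2.0: (1.0, 0.4, 1.0),
                           10.0: (1.0, 0.1, 1.0)},
        seed_spec=(1.0, 100.0),
        replicates=2,
    )
    dataset, truth = syn.generate_aggregation_dataset(
        scenario, syn.NoiseSpec(sigma=0.01, kind="relative", rng_seed=subseed()))
    raw = syn.as_raw_signals(dataset, Smax_inf=1000.0)
    tp.write_trace_csv(raw, out / "tht_raw.csv", kind="raw")
    syn.write_truth(truth, out / "tht_truth.json")

    instrument = hyd.InstrumentParams(lambda0=830e-9, theta=150.0)
    q = hyd.scattering_vector(instrument)
    Rs_m = 55e-9
    D = hyd.diffusion_from_radius(Rs_m, instrument.T, instrument.eta)
    curve, dls_truth = syn.generate_autocorrelation(
        beta=0.9, D=D, q=q,
        noise=syn.NoiseSpec(sigma=0.01, kind="absolute", rng_seed=subseed()),
        replicates=20)
    import pandas as pd

    pd.DataFrame({"lag_s": curve.lags, "g2": curve.g2}).to_csv(
        out / "dls.csv", index=False)
    syn.write_truth(dls_truth, out / "dls_truth.json")

    titr_specs = {"DNAJB1_fibril": 1.7, "DNAJA2_fibril": 7.6}
    titr_entries = {}
    for label, kd in titr_specs.items():
        tcurve, ttruth = syn.generate_titration(
            KD=kd, noise=syn.NoiseSpec(sigma=0.02, kind="relative",
                                       rng_seed=subseed()))
        bd.write_titration_csv(tcurve, out / f"titration_{label}.csv")
        syn.write_truth(ttruth, out / f"titration_{label}_truth.json")
        titr_entries[label] = f"titration_{label}.csv"

    records, nmr_truth = syn.generate_nmr_table(
        noise=syn.NoiseSpec(sigma=0.02, kind="relative", rng_seed=subseed()))
    bd.write_peak_table(records, out / "nmr_peaks.csv")
    syn.write_truth(nmr_truth, out / "nmr_truth.json")

    config = {
        "out_dir": "results",
        "stages": {s: True for s in _STAGES},
        "inputs": {
            "raw_traces_csv": "tht_raw.csv",
            "dls_csv": "dls.csv",
            "titrations": titr_entries,
            "nmr_csv": "nmr_peaks.csv",
        },
        "prep": {"bin_size": 1, "plateau_fraction": 0.1},
        "fit": {"rng_seed": seed, "max_iterations": 30, "popsize": 10,
                "tolerance": 1e-3, "grid_points": 21},
        "seed": {"L": 100.0, "b_nm": 10.0,
                 "spacing_nm": hyd.DEFAULT_MONOMER_SPACING_NM},
        "instrument": {"lambda0_m": instrument.lambda0,
                       "theta_deg": instrument.theta, "n": instrument.n,
                       "T_K": instrument.T, "eta_Pa_s": instrument.eta},
        "nc": 2,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out
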