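"""Chaperone–tau binding analysis.

Two experimental readouts are supported:

* fluorescence anisotropy titrations of a fixed, fluorescently labelled
  species against increasing ligand, fitted with a one-site binding model
  r(c) = r_free + (r_bound − r_free)·c/(KD + c);

* per-residue NMR observables — combined chemical shift perturbations
  Δδ = sqrt(ΔδH² + (ΔδN/5)²) and bound/free intensity ratios I/I0 — with
  one-standard-deviation significance thresholds and contiguous-run region
  calling to map binding footprints on the tau sequence.

The hyperbolic (depletion-free) one-site form is the default because the
labelled species (typically 0.1 µM) sits far below the µM-scale dissociation
constants; the exact quadratic form is available for tight binders.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model as LmModel

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "TitrationCurve",
    "OneSiteFit",
    "OneSiteBindingModel",
    "PeakRecord",
    "BindingProfile",
    "fit_one_site",
    "compute_csp",
    "flag_significant_csp",
    "intensity_ratio_profile",
    "call_binding_regions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TitrationCurve:
    """A fluorescence anisotropy titration."""

    ligand_conc: np.ndarray  # µM, increasing
    anisotropy: np.ndarray
    labeled_conc: float = 0.1  # µM

    def __post_init__(self):
        c = np.asarray(self.ligand_conc, float)
        r = np.asarray(self.anisotropy, float)
        if c.shape != r.shape or c.ndim != 1 or c.size < 6:
            raise InvalidInputError("need >= 6 equal-length titration points")
        if np.any(c < 0):
            raise InvalidInputError("ligand concentrations must be >= 0")
        if np.any(np.diff(c) < 0):
            raise InvalidInputError("ligand concentrations must be non-decreasing")
        object.__setattr__(self, "ligand_conc", c)
        object.__setattr__(self, "anisotropy", r)


@dataclass(frozen=True)
class OneSiteFit:
    """One-site binding fit result.

    ``identifiable`` is False when the fitted amplitude does not exceed
    three times the residual noise — the 'no binding observed' outcome.
    KD and its stderr are NaN in that case.
    """

    KD: float  # µM
    r_free: float
    r_bound: float
    KD_stderr: float
    identifiable: bool

    def summary(self) -> str:
        if not self.identifiable:
            return ("One-site binding fit\n" + "=" * 36 +
                    "\nno binding detected (amplitude < 3x noise)")
        se = "" if not np.isfinite(self.KD_stderr) else f" ± {self.KD_stderr:.3g}"
        return (
            "One-site binding fit\n" + "=" * 36 + "\n"
            f"KD       {self.KD:>12.4g}{se}  uM\n"
            f"r_free   {self.r_free:>12.5g}\n"
            f"r_bound  {self.r_bound:>12.5g}"
        )

    def to_dict(self) -> dict:
        return {
            "KD_uM": self.KD,
            "KD_stderr_uM": self.KD_stderr,
            "r_free": self.r_free,
            "r_bound": self.r_bound,
            "identifiable": self.identifiable,
        }


def _hyperbolic(c, KD, r_free, r_bound):
    return r_free + (r_bound - r_free) * c / (KD + c)


def _quadratic_exact(c, KD, r_free, r_bound, labeled):
    # exact bound fraction with ligand depletion of the labelled species
    s = labeled + c + KD
    bound = (s - np.sqrt(s**2 - 4.0 * labeled * c)) / (2.0 * labeled)
    return r_free + (r_bound - r_free) * bound


class OneSiteBindingModel:
    """Model object for a one-site anisotropy titration.

    ``form`` selects the hyperbolic (default) or exact quadratic binding
    function; ``fit`` returns an :class:`OneSiteFit`.
    """

    def __init__(self, curve: TitrationCurve, form: str = "hyperbolic"):
        if form not in ("hyperbolic", "quadratic"):
            raise InvalidInputError(f"unknown form {form!r}")
        self.curve = curve
        self.form = form

    def fit(self) -> OneSiteFit:
        c, r = self.curve.ligand_conc, self.curve.anisotropy
        if np.ptp(c) == 0:
            raise InvalidInputError("titration spans a single concentration")

        if self.form == "hyperbolic":
            lm = LmModel(_hyperbolic)
        else:
            lm = LmModel(
                lambda c, KD, r_free, r_bound: _quadratic_exact(
                    c, KD, r_free, r_bound, self.curve.labeled_conc)
            )
        span = r[-1] - r[0]
        cpos = c[c > 0]
        kd0 = float(np.median(cpos)) if cpos.size else 1.0
        pars = lm.make_params(KD=kd0, r_free=float(r[0]), r_bound=float(r[-1] + 0.1 * span))
        pars["KD"].set(min=1e-6, max=1e6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = lm.fit(r, pars, c=c)
        # identifiability is judged on the amplitude actually spanned by the
        # measured range, not the (possibly extrapolated) full amplitude
        kd_fit = out.params["KD"].value
        amp_full = out.params["r_bound"].value - out.params["r_free"].value
        spanned = abs(amp_full) * c[-1] / (kd_fit + c[-1])
        noise = float(np.std(out.residual)) if out.residual is not None else 0.0
        identifiable = bool(out.success and spanned > 3.0 * noise and spanned > 0)
        if not identifiable:
            return OneSiteFit(KD=float("nan"), r_free=float(np.mean(r)),
                              r_bound=float(np.mean(r)), KD_stderr=float("nan"),
                              identifiable=False)
        # local wiggles are expected noise; only gross non-monotonicity warns
        monotone_frac = np.mean(np.diff(r) * np.sign(span if span != 0 else 1) >= -3 * noise)
        if monotone_frac < 0.6:
            warnings.warn("titration is grossly non-monotone; fit may be unreliable",
                          stacklevel=2)
        kd = out.params["KD"]
        return OneSiteFit(
            KD=float(kd.value),
            r_free=float(out.params["r_free"].value),
            r_bound=float(out.params["r_bound"].value),
            KD_stderr=float("nan") if kd.stderr is None else float(kd.stderr),
            identifiable=True,
        )


def fit_one_site(curve: TitrationCurve, form: str = "hyperbolic") -> OneSiteFit:
    """Fit a one-site binding model to an anisotropy titration."""
    return OneSiteBindingModel(curve, form=form).fit()


# ---------------------------------------------------------------------------
# NMR observables


@dataclass(frozen=True)
class PeakRecord:
    """Per-residue amide peak observables from a 1H-15N correlation spectrum."""

    residue: int
    delta_H: float | None = None  # ppm
    delta_N: float | None = None  # ppm
    I: float | None = None  # a.u., bound state
    I0: float | None = None  # a.u., free state


@dataclass(frozen=True)
class BindingProfile:
    """Per-residue binding map derived from intensity ratios."""

    residues: np.ndarray
    ratios: np.ndarray  # I/I0
    significant: np.ndarray  # ratio < mean − 1·SD
    strong_attenuation: np.ndarray  # ratio < 0.5
    regions: tuple  # closed residue intervals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residues,
            "I_over_I0": self.ratios,
            "significant": self.significant,
            "strong_attenuation": self.strong_attenuation,
        })


def compute_csp(records) -> dict[int, float]:
    """Combined chemical shift perturbation per residue.

    Δδ = sqrt(ΔδH² + (ΔδN/5)²); residues lacking either shift are skipped
    (logged at DEBUG).
    """
    out: dict[int, float] = {}
    seen = set()
    for rec in records:
        if rec.residue in seen:
            raise InvalidInputError(f"duplicate residue {rec.residue}")
        seen.add(rec.residue)
        if rec.delta_H is None or rec.delta_N is None:
            logger.debug("residue %d missing shift pair; skipped", rec.residue)
            continue
        out[rec.residue] = float(np.hypot(rec.delta_H, rec.delta_N / 5.0))
    return out


def flag_significant_csp(csps: dict[int, float]) -> dict[int, bool]:
    """Flag residues with Δδ above mean + 1 SD of all quantified residues."""
    if len(csps) < 5:
        raise InsufficientDataError("need >= 5 residues with CSPs")
    vals = np.array(list(csps.values()))
    thr = vals.mean() + vals.std(ddof=0)
    if np.allclose(vals, vals[0]):
        return {r: False for r in csps}
    return {r: bool(v > thr) for r, v in csps.items()}


def intensity_ratio_profile(records, min_run: int = 3,
                            bridge_gaps: bool = True) -> BindingProfile:
    """Per-residue I/I0 profile with 1-SD significance and 0.5 attenuation flags.

    Residues with I0 = 0 are excluded with a warning.  Significance means
    the ratio falls below mean − 1·SD of all quantified ratios; ratios below
    0.5 additionally carry the strong-attenuation flag (intermolecular
    interaction).  Binding regions are maximal runs of significant residues
    (see :func:`call_binding_regions`).
    """
    residues, ratios = [], []
    for rec in sorted(records, key=lambda r: r.residue):
        if rec.I is None or rec.I0 is None:
            continue
        if rec.I0 == 0:
            warnings.warn(f"residue {rec.residue} has I0 = 0; excluded", stacklevel=2)
            continue
        residues.append(rec.residue)
        ratios.append(rec.I / rec.I0)
    residues = np.asarray(residues, int)
    ratios = np.asarray(ratios, float)
    if np.any(ratios < 0):
        raise InvalidInputError("negative intensity ratio")
    if ratios.size == 0:
        raise InvalidInputError("no quantifiable residues")
    thr = ratios.mean() - ratios.std(ddof=0)
    significant = (ratios < thr) if ratios.std(ddof=0) > 0 else np.zeros(ratios.size, bool)
    strong = ratios < 0.5
    profile = BindingProfile(residues, ratios, significant, strong, regions=())
    regions = call_binding_regions(profile, min_run=min_run, bridge_gaps=bridge_gaps)
    return BindingProfile(residues, ratios, significant, strong, regions=tuple(regions))


def call_binding_regions(profile: BindingProfile, min_run: int = 3,
                         bridge_gaps: bool = True) -> list[tuple[int, int]]:
    """Maximal runs of consecutive significant residues as closed intervals.

    Runs shorter than ``min_run`` are dropped; with ``bridge_gaps`` a single
    non-significant residue inside a run is bridged before run lengths are
    measured.
    """
    if min_run < 1:
        raise InvalidInputError(f"min_run must be >= 1, got {min_run}")
    res = np.asarray(profile.residues, int)
    sig = np.asarray(profile.significant, bool)
    if res.size == 0 or not sig.any():
        return []
    flagged = {int(r) for r in res[sig]}
    if bridge_gaps:
        for r in sorted({int(r) for r in res} - flagged):
            if (r - 1) in flagged and (r + 1) in flagged:
                flagged.add(r)
    regions = []
    ordered = sorted(flagged)
    start = prev = ordered[0]
    for r in ordered[1:] + [None]:
        if r is not None and r == prev + 1:
            prev = r
            continue
        if prev - start + 1 >= min_run:
            regions.append((start, prev))
        if r is not None:
            start = prev = r
    return regions


# ---------------------------------------------------------------------------
# tabular IO


def read_peak_table(path) -> list[PeakRecord]:
    """Read a peak-table CSV: residue, ddH_ppm, ddN_ppm, I, I0."""
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        def val(col):
            return None if col not in df.columns or pd.isna(row[col]) else float(row[col])
        recs.append(PeakRecord(residue=int(row["residue"]),
                               delta_H=val("ddH_ppm"), delta_N=val("ddN_ppm"),
                               I=val("I"), I0=val("I0")))
    return recs


def write_peak_table(records, path) -> None:
    rows = [{"residue": r.residue, "ddH_ppm": r.delta_H, "ddN_ppm": r.delta_N,
             "I": r.I, "I0": r.I0} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titration_csv(path, labeled_conc: float = 0.1) -> TitrationCurve:
    """Read a titration CSV: conc_uM, anisotropy."""
    df = pd.read_csv(path).sort_values("conc_uM")
    return TitrationCurve(df["conc_uM"].to_numpy(float),
                          df["anisotropy"].to_numpy(float),
                          labeled_conc=labeled_conc)


def write_titration_csv(curve: TitrationCurve, path) -> None:
    pd.DataFrame({"conc_uM": curve.ligand_conc,
                  "anisotropy": curve.anisotropy}).to_csv(path, index=False)


def profile_report(profile: BindingProfile, path) -> None:
    """Write the per-residue profile CSV plus a JSON region report."""
    profile.to_frame().to_csv(str(path) + ".csv", index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"regions": [list(r) for r in profile.regions]}, fh, indent=2)
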