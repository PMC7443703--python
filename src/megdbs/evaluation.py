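"""Sensor-level evaluation: band RMSE, parameter sweeps, robustness and
optimal-parameter selection.

Cleaning quality is measured as the root mean squared relative error of the
per-channel band-averaged log10 power between the cleaned full-artefact
(DSMW) recording and the reference recording,

    RMSE(band) = sqrt( mean_i [ (pi_i^cleaned - pi_i^ref) / pi_i^ref ]^2 )

evaluated in three bands: the dipole band (11.5-12.5 Hz), the DBS band
(detected peak +/- 1 Hz) and the movement band (1-15 Hz excluding
11.5-12.5 Hz).  Each method is swept over its strength parameter (Hampel C,
S3P noise-subspace size, ICA-MI rejection rate, tSSS correlation limit);
robustness is the mean +/- SD of RMSE over the sweep, and the optimal
sensor-level parameter minimises the average RMSE across the three bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Recording
from .phantom import ConditionSet
from .spectral import SpectrumEstimate, BandPowerSummary, welch_psd, band_log_power
from .cleaning import (HampelParams, ICAMIParams, S3PParams, TSSSParams,
                       baseline_correct, dbs_harmonic_bands,
                       ica_mi_decompose, ica_mi_reconstruct,
                       tsss_decompose, tsss_assemble)
from .cleaning.hampel import HampelCache
from .cleaning.s3p import S3PCache

BAND_NAMES = ("dipole", "movement", "dbs")

DEFAULT_SWEEPS = {
    "hampel": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
    "s3p": [1, 2, 3, 4, 5, 6, 7, 8, 9],
    "icami": [5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0],
    "tsss": [0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60],
}

PARAMETER_NAMES = {"hampel": "C", "s3p": "NS", "icami": "R", "tsss": "CL"}

# direction of "weaker cleaning" used for tie-breaking in optimal selection
_WEAKER_IS_LARGER = {"hampel": True, "s3p": False, "icami": False, "tsss": True}


def preprocess_conditions(cset: ConditionSet, base: float = 50.0,
                          max_harmonic: float = 550.0) -> ConditionSet:
    """Notch power-line noise out of all four recordings.

    Line removal must precede cleaning and evaluation: the line sinusoids
    share a common period with the stimulation pulse train, so they carry
    genuine mutual information with the DBS reference signal and would bias
    the ICA-MI selection (and the band errors around the notched bins).
    """
    from .spectral import notch_filter

    return ConditionSet(
        reference=notch_filter(cset.reference, base, max_harmonic),
        dmw=notch_filter(cset.dmw, base, max_harmonic),
        dsmw=notch_filter(cset.dsmw, base, max_harmonic),
        empty_room=notch_filter(cset.empty_room, base, max_harmonic),
        dbs_reference_channel=cset.dbs_reference_channel,
        config=cset.config)


@dataclass
class BandSet:
    """The three evaluation bands around a detected DBS peak frequency."""

    f_peak: float
    dipole: tuple = ((11.5, 12.5),)
    movement: tuple = ((1.0, 11.5), (12.5, 15.0))
    dbs: tuple = ()

    def __post_init__(self):
        if not self.dbs:
            self.dbs = ((self.f_peak - 1.0, self.f_peak + 1.0),)

    def items(self):
        return (("dipole", self.dipole), ("movement", self.movement),
                ("dbs", self.dbs))


@dataclass
class RMSEResult:
    band: str
    value: float
    n_channels: int


@dataclass
class SweepResult:
    """RMSE (and optionally source overlap D) as a function of a method's
    strength parameter."""

    method: str
    parameter_name: str
    parameter_values: np.ndarray
    rmse: pd.DataFrame                  # index: band, columns: parameter value
    baseline: dict                      # band -> uncleaned DSMW RMSE
    d: pd.Series | None = None
    failures: dict = field(default_factory=dict)

    @property
    def best_sensor_value(self):
        return select_optimal_sensor(self)


def detect_dbs_peak(spec: SpectrumEstimate, search=(120.0, 140.0)) -> float:
    """Frequency of the maximum channel-mean power inside ``search``.

    Raises when no bin exceeds twice the median in-band power (no DBS peak,
    e.g. in the reference condition).
    """
    mask = (spec.freqs >= search[0]) & (spec.freqs <= search[1])
    if not mask.any():
        raise ValueError("search interval outside the frequency axis")
    mean_p = spec.power.mean(axis=0)[mask]
    if mean_p.max() <= 2.0 * np.median(mean_p):
        raise ValueError(f"no DBS peak found in {search}")
    return float(spec.freqs[mask][np.argmax(mean_p)])


def rmse_band(clean: BandPowerSummary, ref: BandPowerSummary) -> RMSEResult:
    """Root mean squared relative error of band log power across channels."""
    if clean.n_channels != ref.n_channels:
        raise ValueError("summaries cover different channel counts")
    if clean.band != ref.band:
        raise ValueError("summaries cover different bands")
    if np.any(ref.pi == 0):
        raise ValueError("reference band log power is zero on some channel; "
                         "the relative error is undefined")
    err = (clean.pi - ref.pi) / ref.pi
    return RMSEResult(band="", value=float(np.sqrt(np.mean(err**2))),
                      n_channels=clean.n_channels)


def _band_rmses(clean_spec: SpectrumEstimate, ref_spec: SpectrumEstimate,
                bands: BandSet) -> dict:
    out = {}
    for name, band in bands.items():
        r = rmse_band(band_log_power(clean_spec, band),
                      band_log_power(ref_spec, band))
        out[name] = RMSEResult(band=name, value=r.value, n_channels=r.n_channels)
    return out


def evaluate_cleaning(cset: ConditionSet, cleaned: Recording, bands: BandSet,
                      apply_baseline: bool = False,
                      ref_spec: SpectrumEstimate | None = None,
                      dsmw_spec: SpectrumEstimate | None = None) -> dict:
    """Band RMSE of a cleaned DSMW recording plus the uncleaned baseline.

    Returns ``{"rmse": {band: RMSEResult}, "baseline": {band: RMSEResult}}``.
    With ``apply_baseline`` the cleaned spectrum is baseline-corrected
    against the reference before the band powers are taken (the tSSS
    convention).
    """
    if ref_spec is None:
        ref_spec = welch_psd(cset.reference)
    if dsmw_spec is None:
        dsmw_spec = welch_psd(cset.dsmw)
    clean_spec = welch_psd(cleaned)
    if apply_baseline:
        clean_spec = baseline_correct(clean_spec, ref_spec)
    return {"rmse": _band_rmses(clean_spec, ref_spec, bands),
            "baseline": _band_rmses(dsmw_spec, ref_spec, bands)}


def _clean_series(method: str, values, cset: ConditionSet, f_peak: float,
                  seed: int = 0, mode: str = "dbs_band",
                  apply_baseline: bool = False):
    """Yield (value, cleaned Recording or exception) reusing whatever can be
    shared across the sweep (ICA decomposition, tSSS segment fits)."""
    dsmw = cset.dsmw
    if method == "hampel":
        cache = HampelCache(dsmw, HampelParams(mode=mode), f_peak=f_peak)
        for v in values:
            yield v, dsmw.copy_with(cache.apply(float(v)))
    elif method == "s3p":
        cache = S3PCache(dsmw, S3PParams(mode=mode), f_peak=f_peak,
                         k_max=int(max(values)))
        for v in values:
            yield v, dsmw.copy_with(cache.apply(int(v)))
    elif method == "icami":
        dec = ica_mi_decompose(dsmw, cset.dbs_reference_channel,
                               ICAMIParams(seed=seed,
                                           notch_freq=cset.config.f_dipole))
        for v in values:
            yield v, dsmw.copy_with(ica_mi_reconstruct(dec, float(v)))
    elif method == "tsss":
        segments = tsss_decompose(dsmw, TSSSParams())
        for v in values:
            yield v, dsmw.copy_with(tsss_assemble(segments, float(v)))
    else:
        raise ValueError(f"unknown method {method!r}")


def sweep(method: str, values, cset: ConditionSet, bands: BandSet,
          seed: int = 0, mode: str = "dbs_band",
          apply_baseline: bool | None = None) -> SweepResult:
    """Run one cleaning method across its parameter range and collect the
    three band RMSEs per value.

    ``apply_baseline`` defaults to True for tSSS (whose broadband power
    shift would otherwise dominate the band errors) and False elsewhere.
    """
    if apply_baseline is None:
        apply_baseline = method == "tsss"
    values = list(values)
    ref_spec = welch_psd(cset.reference)
    dsmw_spec = welch_psd(cset.dsmw)
    baseline = {name: r.value
                for name, r in _band_rmses(dsmw_spec, ref_spec, bands).items()}
    rmse = pd.DataFrame(index=list(BAND_NAMES), columns=values, dtype=float)
    failures = {}
    for v, cleaned in _clean_series(method, values, cset, bands.f_peak,
                                    seed=seed, mode=mode):
        try:
            clean_spec = welch_psd(cleaned)
            if apply_baseline:
                clean_spec = baseline_correct(clean_spec, ref_spec)
            for name, band in bands.items():
                r = rmse_band(band_log_power(clean_spec, band),
                              band_log_power(ref_spec, band))
                rmse.loc[name, v] = r.value
        except Exception as exc:  # record and continue the sweep
            failures[v] = repr(exc)
    return SweepResult(method=method, parameter_name=PARAMETER_NAMES[method],
                       parameter_values=np.asarray(values, dtype=float),
                       rmse=rmse, baseline=baseline, failures=failures)


def robustness(sw: SweepResult, bands_used=None):
    """Mean and sample SD of RMSE over the parameter range.

    By convention the statistics cover the DBS band only for Hampel and S3P
    (the bands those methods touch in their default mode) and all three
    bands pooled for ICA-MI and tSSS.
    """
    if bands_used is None:
        bands_used = (("dbs",) if sw.method in ("hampel", "s3p")
                      else tuple(BAND_NAMES))
    vals = sw.rmse.loc[list(bands_used)].to_numpy(dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least two RMSE values for a spread estimate")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def select_optimal_sensor(sw: SweepResult):
    """Parameter value with the lowest average RMSE across the three bands.

    Exact ties are broken toward the weaker-cleaning end of the range
    (larger C, smaller noise subspace, smaller R, larger CL).
    """
    avg = sw.rmse.mean(axis=0)
    avg = avg[np.isfinite(avg.to_numpy(dtype=float))]
    if avg.empty:
        raise ValueError("sweep produced no usable RMSE values")
    best = avg.min()
    candidates = [v for v in avg.index if avg[v] == best]
    return (max(candidates) if _WEAKER_IS_LARGER.get(sw.method, True)
            else min(candidates))


def select_optimal_source(values, d_values, improvement: float = 0.01):
    """Walk the parameter sequence while D keeps improving by more than
    ``improvement``; return the last accepted value.

    ``values`` must be in sweep order starting from the method's initial
    value.
    """
    values = list(values)
    d_values = list(d_values)
    if not values or len(values) != len(d_values):
        raise ValueError("need matching, non-empty parameter and D sequences")
    best = values[0]
    d_prev = d_values[0]
    for v, d in zip(values[1:], d_values[1:]):
        if d - d_prev > improvement:
            best, d_prev = v, d
        else:
            break
    return best


# ---------------------------------------------------------------------------
# reporting

@dataclass
class Report:
    """Tabular summary of a full evaluation run (sweeps, robustness, D)."""

    tables: dict

    def save(self, out_dir):
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = {}
        for name, df in self.tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, float_format="%.17g")
            names[name] = path.name
        (out / "report.json").write_text(json.dumps({"tables": names}, indent=2))

    @classmethod
    def load(cls, out_dir):
        import json
        from pathlib import Path

        out = Path(out_dir)
        meta = json.loads((out / "report.json").read_text())
        tables = {name: pd.read_csv(out / fname, index_col=0,
                                    float_precision="round_trip")
                  for name, fname in meta["tables"].items()}
        return cls(tables=tables)


def make_report(cset: ConditionSet, sweeps: dict,
                d_results: dict | None = None,
                spectra: dict | None = None) -> Report:
    """Assemble RMSE sweeps, robustness statistics, optimal parameters and
    (optionally) source-overlap values into one set of tables."""
    tables = {}
    rob_rows = []
    opt_rows = []
    for method, sw in sweeps.items():
        df = sw.rmse.copy()
        df.columns = [f"{sw.parameter_name}={v:g}" for v in df.columns]
        for band, val in sw.baseline.items():
            df.loc[band, "uncleaned"] = val
        tables[f"rmse_{method}"] = df
        mean, sd = robustness(sw)
        rob_rows.append({"method": method, "mean": mean, "sd": sd})
        opt_rows.append({"method": method,
                         "parameter": sw.parameter_name,
                         "best_sensor_value": sw.best_sensor_value})
    tables["robustness"] = pd.DataFrame(rob_rows).set_index("method")
    tables["optimal_sensor"] = pd.DataFrame(opt_rows).set_index("method")
    if d_results:
        tables["overlap_d"] = pd.DataFrame(
            [{"dataset": k, "d": v.d, "n_intersection": v.n_intersection,
              "n_union": v.n_union} for k, v in d_results.items()]
        ).set_index("dataset")
    if spectra:
        rows = {}
        for name, spec in spectra.items():
            rows[name] = np.mean(np.log10(spec.power), axis=0)
        freqs = next(iter(spectra.values())).freqs
        tables["mean_log_spectra"] = pd.DataFrame(rows, index=freqs)
    return Report(tables=tables)


def plot_report(report: Report, out_dir):
    """Bar/line plots of the report tables (saved as PNG files)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        fig, ax = plt.subplots(figsize=(8, 4))
        if name == "mean_log_spectra":
            df.plot(ax=ax)
            ax.set_xlabel("frequency (Hz)")
            ax.set_ylabel("mean log10 power")
        elif name.startswith("rmse_"):
            df.T.plot.bar(ax=ax)
            ax.set_ylabel("RMSE")
        else:
            df.plot.bar(ax=ax)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=100)
        plt.close(fig)
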