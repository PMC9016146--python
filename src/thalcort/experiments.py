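"""Declarative experiment runner: base state, lesions, band transitions, ScZ.

Each experiment builds the network (base + scheme + lesions), generates the
per-trial stimuli, runs the trial batch, and pushes the voltages through the
spectral pipeline.  Conditions that are compared share ``seed0``, so the two
members of every trial pair consume identical noise realizations and the
paired t-test isolates the effect of the scheme edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .network import (
    INTERLAYER_LESION,
    LGN_ISOLATION_LESION,
    LesionSet,
    StateScheme,
    apply_lesion,
    apply_scheme,
    build_base_network,
    make_scheme,
)
from .simulate import SimulationConfig, run_trials
from .spectral import (
    BAND_ORDER,
    BANDS,
    BETA_BAND,
    BandPowerTable,
    PairedTestResult,
    SpectrumRecord,
    band_power,
    band_power_table,
    dominant_band,
    paired_ttest,
    peak_frequency,
)
from .stimuli import PulseConfig

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "run_experiment",
    "compare",
    "run_transition",
    "run_scz",
    "EXPERIMENTS",
]

#: populations whose outputs stand for the recorded signal
DEFAULT_OUTPUTS = ("TCR", "Py4", "Py6")

#: SSVEP flicker amplitude default: midpoint of the tested 5-10 mV range
SSVEP_AMPLITUDE = 7.0


@dataclass
class ExperimentSpec:
    name: str
    scheme: str = "base"  # named state scheme
    lesions: Optional[LesionSet] = None
    pulse_hz: Optional[float] = None  # SSVEP flicker on Ret, None = noise only
    pulse_amplitude: float = SSVEP_AMPLITUDE
    outputs: Sequence[str] = DEFAULT_OUTPUTS
    control: Optional[str] = None  # name of the paired control experiment


#: the named experiment suite
EXPERIMENTS: Dict[str, ExperimentSpec] = {
    "base": ExperimentSpec("base"),
    "lesion-lgn": ExperimentSpec("lesion-lgn", lesions=LGN_ISOLATION_LESION),
    "lesion-lgn-interlayer": ExperimentSpec(
        "lesion-lgn-interlayer",
        lesions=LGN_ISOLATION_LESION + INTERLAYER_LESION,
    ),
    "theta": ExperimentSpec("theta", scheme="theta", control="base"),
    "alpha": ExperimentSpec("alpha", scheme="alpha", control="base"),
    "beta": ExperimentSpec("beta", scheme="beta", control="base"),
    "scz-resting": ExperimentSpec("scz-resting", scheme="scz", control="beta"),
    "beta-ssvep17": ExperimentSpec("beta-ssvep17", scheme="beta", pulse_hz=17.0),
    "scz-ssvep17": ExperimentSpec(
        "scz-ssvep17", scheme="scz", pulse_hz=17.0, control="beta-ssvep17"
    ),
}


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    band_powers: BandPowerTable
    spectra: Dict[str, SpectrumRecord]  # trial-mean PSD per population
    voltage_means: Dict[str, float]  # time- and trial-mean, over clipped window
    sim: SimulationConfig

    def dominant_bands(self) -> Dict[str, str]:
        return {
            p: dominant_band(self.band_powers.table.loc[p])
            for p in self.spec.outputs
        }

    def peak_frequencies(self) -> Dict[str, float]:
        return {p: peak_frequency(self.spectra[p]) for p in self.spec.outputs}

    def summary(self) -> pd.DataFrame:
        df = self.band_powers.table.copy()
        df["dominant"] = [self.dominant_bands()[p] for p in df.index]
        df["peak_Hz"] = [self.peak_frequencies()[p] for p in df.index]
        df["mean_mV"] = [self.voltage_means[p] for p in df.index]
        return df


def _clipped_mean(rec, population: str, dt: float = 1e-3) -> float:
    n = int(round(1.0 / dt))
    return float(rec.voltage(population)[n:-n].mean())


def run_experiment(
    spec: ExperimentSpec,
    cfg: SimulationConfig,
    model_config: ModelConfig | None = None,
) -> ExperimentResult:
    """Build, simulate and analyze one experimental condition."""
    mc = model_config if model_config is not None else DEFAULT_CONFIG
    net = build_base_network(mc)
    if spec.scheme != "base":
        net = apply_scheme(net, make_scheme(spec.scheme, mc))
    if spec.lesions is not None:
        net = apply_lesion(net, spec.lesions)
    pulse = None
    if spec.pulse_hz is not None:
        pulse = PulseConfig(
            frequency=spec.pulse_hz,
            amplitude=spec.pulse_amplitude,
            duration=cfg.duration,
            dt=cfg.dt_report,
        )
    records = run_trials(net, cfg, pulse=pulse)
    bpt, spectra = band_power_table(records, spec.outputs)
    vmeans = {
        p: float(np.mean([_clipped_mean(r, p, cfg.dt_report) for r in records]))
        for p in spec.outputs
    }
    return ExperimentResult(
        spec=spec, band_powers=bpt, spectra=spectra, voltage_means=vmeans,
        sim=cfg,
    )


def compare(
    test: ExperimentResult,
    control: ExperimentResult,
    population: str = "Py4",
    bands: Sequence = BAND_ORDER,
) -> Dict[str, PairedTestResult]:
    """Per-band paired t-tests of ``test`` vs ``control`` band powers.

    Both results must come from runs with identical trial seeds (checked).
    ``mean_diff > 0`` means more power in ``test`` than in ``control``.
    """
    if test.sim.seed0 != control.sim.seed0 or test.sim.n_trials != control.sim.n_trials:
        raise ValueError("compared conditions must share trial seeds (paired design)")
    x = control.band_powers.per_trial[population]
    y = test.band_powers.per_trial[population]
    out = {}
    for b in bands:
        if isinstance(b, str):
            j = BAND_ORDER.index(b)
            out[b] = paired_ttest(x[:, j], y[:, j])
        else:
            # aggregate band given as (lo, hi): sum the member bands
            members = [
                j for j, name in enumerate(BAND_ORDER)
                if b[0] <= BANDS[name][0] and BANDS[name][1] <= b[1]
            ]
            out[b] = paired_ttest(x[:, members].sum(axis=1), y[:, members].sum(axis=1))
    return out


def run_transition(
    band: str,
    cfg: SimulationConfig,
    model_config: ModelConfig | None = None,
) -> Tuple[ExperimentResult, Dict[str, str]]:
    """Run a named band-transition scheme and report the dominant bands.

    A dominance mismatch is reported, not raised: the caller (or the test
    suite) decides whether it is a failure.
    """
    if band not in ("theta", "alpha", "beta"):
        raise ValueError(f"unknown transition {band!r}")
    res = run_experiment(EXPERIMENTS[band], cfg, model_config)
    return res, res.dominant_bands()


def run_scz(
    mode: str,
    cfg: SimulationConfig,
    model_config: ModelConfig | None = None,
    population: str = "Py4",
) -> Dict[str, object]:
    """Schizophrenia condition vs its beta-state control, shared seeds.

    ``mode`` is ``"resting"`` (noise-only) or ``"ssvep17"`` (17 Hz flicker on
    the retinal node in both conditions).  Returns the two results plus the
    paired tests on theta and total beta (beta-low + beta-high) band power of
    the chosen output population.
    """
    if mode == "resting":
        ctl_spec, scz_spec = EXPERIMENTS["beta"], EXPERIMENTS["scz-resting"]
    elif mode == "ssvep17":
        ctl_spec, scz_spec = EXPERIMENTS["beta-ssvep17"], EXPERIMENTS["scz-ssvep17"]
    else:
        raise ValueError(f"unknown ScZ mode {mode!r}")
    control = run_experiment(ctl_spec, cfg, model_config)
    scz = run_experiment(scz_spec, cfg, model_config)
    x = control.band_powers.per_trial[population]
    y = scz.band_powers.per_trial[population]
    i_th = BAND_ORDER.index("theta")
    i_bl, i_bh = BAND_ORDER.index("beta-low"), BAND_ORDER.index("beta-high")
    tests = {
        "theta": paired_ttest(x[:, i_th], y[:, i_th]),
        "beta": paired_ttest(
            x[:, i_bl] + x[:, i_bh], y[:, i_bl] + y[:, i_bh]
        ),
    }
    return {"control": control, "scz": scz, "tests": tests}
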