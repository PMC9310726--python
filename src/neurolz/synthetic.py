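"""Synthetic electrocorticogram generator.

No public recordings exist for the cat dataset this analysis targets, so
the pipeline is exercised on surrogate data with the same statistical
structure:

* **signal mode** — per-epoch waveforms built from four spectral
  ingredients (slow oscillation 0.5-4 Hz, burst-gated spindles 7-14 Hz,
  narrowband gamma 30-45 Hz, 1/f broadband noise) with state-specific
  weights. Slow-wave sleep is slow-dominated, light sleep intermediate
  with spindle bursts, wakefulness and REM broadband/gamma-dominated and
  nearly identical — which is exactly the qualitative spectral layout the
  complexity analysis relies on.
* **direct-value mode** — per-epoch complexity values drawn straight from
  the hierarchical linear model ``C = b0 + b1*d + b2*d^2 (+ stim) +
  u_cat + u_session + eps`` with dose centred at 7.5 mg/kg, for fast
  statistical tests of the inference layer.

Every draw is governed by a single seed through ``numpy.random.SeedSequence``
spawning, so a configuration plus seed reproduces any dataset bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .lz import epoch_lz
from .preprocess import (
    ConditionLabel,
    Recording,
    SignalEpoch,
    SLEEP_STATES,
    bandpass,
)

__all__ = ["SyntheticConfig", "gen_state_epoch", "gen_sleep_dataset", "gen_dose_dataset"]

DOSE_CENTER = 7.5  # mg/kg; decorrelates linear and quadratic dose terms

#: Spectral mixture weights per sleep state (relative amplitudes of the
#: slow, spindle, gamma and broadband ingredients). Chosen so that the
#: binarized-LZ means land in the empirically observed envelope
#: (wake-like states ~0.5-0.7, slow-wave sleep well below) with the
#: ordering SWS < LS < {W, REM} and W/REM nearly indistinguishable.
DEFAULT_STATE_MIXTURES: dict[str, dict[str, float]] = {
    "W": {"a_slow": 0.25, "a_spindle": 0.0, "a_gamma": 0.6, "a_broadband": 1.0},
    "REM": {"a_slow": 0.30, "a_spindle": 0.0, "a_gamma": 0.55, "a_broadband": 1.0},
    "LS": {"a_slow": 1.2, "a_spindle": 0.9, "a_gamma": 0.3, "a_broadband": 0.6},
    "SWS": {"a_slow": 3.0, "a_spindle": 0.3, "a_gamma": 0.15, "a_broadband": 0.35},
}

#: Dose-response coefficients (on centred dose, per mg/kg) per shape.
SHAPE_COEFFS: dict[str, tuple[float, float]] = {
    "inverted_u": (0.0, -0.0008),
    "u": (0.0, 0.0008),
    "linear": (0.003, 0.0),
    "flat": (0.0, 0.0),
}


@dataclass
class SyntheticConfig:
    """Full parameterization of the generative model.

    Defaults mirror the reference study's design: 1024 Hz sampling, 5-s
    epochs (5120 samples), 60 epochs per 300-s condition selection, four
    sessions per ketamine dose, doses {0, 5, 10, 15} mg/kg centred at 7.5.
    """

    fs: float = 1024.0
    epoch_samples: int = 5120
    n_cats: int = 3
    cortices: tuple[str, ...] = ("rPp",)
    flat_cortices: tuple[str, ...] = ()
    sessions_per_dose: int = 4
    epochs_per_condition: int = 60
    state_mixtures: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(w) for s, w in DEFAULT_STATE_MIXTURES.items()}
    )
    # direct-value mode (dose analysis)
    beta0: float = 0.62
    dose_coefficients: tuple[float, float] | None = None  # (b1, b2); None -> shape table
    stim_effect: float = 0.0
    sigma_cat: float = 0.01
    sigma_session: float = 0.005
    sigma_eps: float = 0.02
    # signal mode only: lognormal sd of the per-cat multiplicative weight jitter
    sigma_cat_weights: float = 0.05
    amplitude_uV: float = 50.0
    seed: int = 1234

    def __post_init__(self) -> None:
        for state, w in self.state_mixtures.items():
            if any(v < 0 for v in w.values()):
                raise ValueError(f"negative mixture weight for state {state}")
        for s in (self.sigma_cat, self.sigma_session, self.sigma_eps):
            if s < 0:
                raise ValueError("variance components must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["cortices"] = list(self.cortices)
        d["flat_cortices"] = list(self.flat_cortices)
        return d


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f (pink) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _narrowband_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz (FFT mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    x = np.fft.irfft(spec * mask, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spindle_envelope(
    n: int, fs: float, rng: np.random.Generator,
    mean_burst_s: float = 1.0, mean_gap_s: float = 3.0,
) -> np.ndarray:
    """Two-state on/off gate with exponential burst and gap durations."""
    env = np.zeros(n)
    i = 0
    on = bool(rng.integers(0, 2))
    while i < n:
        dur_s = rng.exponential(mean_burst_s if on else mean_gap_s)
        j = min(n, i + max(1, int(round(dur_s * fs))))
        if on:
            env[i:j] = 1.0
        i = j
        on = not on
    return env


def gen_state_epoch(
    state: str, cfg: SyntheticConfig, rng: np.random.Generator,
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """One epoch of synthetic ECoG for a sleep/wake state, in microvolts.

    ``weights`` overrides the state's default mixture (used for per-cat
    jitter); draws come from ``rng`` so identical generator state gives a
    bit-identical epoch.
    """
    if state not in cfg.state_mixtures:
        raise ValueError(f"unknown state {state!r}; expected one of {SLEEP_STATES}")
    w = weights if weights is not None else cfg.state_mixtures[state]
    n, fs = cfg.epoch_samples, cfg.fs
    t = np.arange(n) / fs

    f_slow = rng.uniform(0.5, 4.0)
    slow = np.sin(2 * np.pi * f_slow * t + rng.uniform(0, 2 * np.pi))

    f_sp = rng.uniform(7.0, 14.0)
    spindle = _spindle_envelope(n, fs, rng) * np.sin(
        2 * np.pi * f_sp * t + rng.uniform(0, 2 * np.pi)
    )

    gamma = _narrowband_noise(n, fs, 30.0, 45.0, rng)
    broadband = _pink_noise(n, rng)

    sig = (
        w["a_slow"] * slow
        + w["a_spindle"] * spindle
        + w["a_gamma"] * gamma
        + w["a_broadband"] * broadband
    )
    return cfg.amplitude_uV * sig


def _cat_weight_jitter(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Per-cat multiplicative (lognormal) jitter applied to every weight."""
    out: dict[str, dict[str, float]] = {}
    for state, w in cfg.state_mixtures.items():
        factors = {k: float(np.exp(rng.normal(0.0, cfg.sigma_cat_weights))) for k in w}
        out[state] = {k: v * factors[k] for k, v in w.items()}
    return out


def gen_sleep_dataset(
    cfg: SyntheticConfig, *, band: tuple[float, float] | None = (0.5, 200.0),
    return_epochs: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[SignalEpoch]]:
    """Hierarchical sleep dataset: cats x cortices x states x epochs.

    Each epoch is synthesized in signal mode, band-pass filtered (unless
    ``band`` is None) and run through the complexity pipeline. Cortices
    listed in ``cfg.flat_cortices`` use the wake mixture for every state,
    modelling a region whose complexity does not track sleep state.

    Returns a long table ``cat, cortex, state, epoch, T, L, C`` (and the
    raw epochs too when ``return_epochs``).
    """
    if cfg.n_cats < 1:
        raise ValueError("n_cats must be >= 1")
    root = np.random.SeedSequence(cfg.seed)
    cat_seeds = root.spawn(cfg.n_cats)
    rows: list[dict[str, Any]] = []
    all_epochs: list[SignalEpoch] = []
    for ci in range(cfg.n_cats):
        cat = f"cat{ci + 1}"
        cat_rng = np.random.Generator(np.random.PCG64(cat_seeds[ci]))
        weights = _cat_weight_jitter(cfg, cat_rng)
        for cortex in cfg.cortices:
            flat = cortex in cfg.flat_cortices
            for state in SLEEP_STATES:
                w = weights["W"] if flat else weights[state]
                for k in range(cfg.epochs_per_condition):
                    samples = gen_state_epoch(state, cfg, cat_rng, weights=w)
                    cond = ConditionLabel(kind="sleep", state=state)
                    if band is not None:
                        rec = Recording(
                            samples=samples[None, :], fs=cfg.fs, channels=(cortex,),
                            cat=cat, session="s1", condition=cond,
                        )
                        samples = bandpass(rec, *band).samples[0]
                    ep = SignalEpoch(
                        samples=samples, fs=cfg.fs, channel=cortex,
                        condition=cond, cat=cat, session="s1", epoch_index=k,
                    )
                    rec_c = epoch_lz(ep.samples, ep.annotations)
                    rows.append(
                        {
                            "cat": cat, "cortex": cortex, "state": state,
                            "epoch": k, "T": rec_c.T, "L": rec_c.L, "C": rec_c.C,
                        }
                    )
                    if return_epochs:
                        all_epochs.append(ep)
    table = pd.DataFrame(rows)
    return (table, all_epochs) if return_epochs else table


def gen_dose_dataset(
    shape: str = "inverted_u",
    cfg: SyntheticConfig | None = None,
    *,
    doses: tuple[int, ...] = (0, 5, 10, 15),
    include_stim: bool = False,
    cortex_offsets: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Direct-value dose-response dataset from the hierarchical model.

    For cat i, session j (nested in cat), epoch k:

    ``C_ijk = b0 + b1*d + b2*d^2 + stim_effect*stim + u_i + u_ij + eps_ijk``

    with ``d`` the dose centred at 7.5 mg/kg and u, eps zero-mean Gaussian
    with standard deviations ``sigma_cat``, ``sigma_session``, ``sigma_eps``.
    ``shape`` selects the sign pattern of (b1, b2) from the built-in table
    unless ``cfg.dose_coefficients`` overrides it. Each cat gets
    ``sessions_per_dose`` sessions at every dose; with ``include_stim``
    half of each session's epochs carry the stimulation flag.

    When ``cortex_offsets`` maps cortex label -> baseline shift, the whole
    design is replicated per cortex with shifted intercepts (used for the
    across-cortex baseline contrast).
    """
    cfg = cfg if cfg is not None else SyntheticConfig()
    if shape not in SHAPE_COEFFS:
        raise ValueError(f"unknown shape {shape!r}; expected one of {sorted(SHAPE_COEFFS)}")
    b1, b2 = (
        cfg.dose_coefficients if cfg.dose_coefficients is not None else SHAPE_COEFFS[shape]
    )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed)))
    offsets = cortex_offsets if cortex_offsets is not None else {"all": 0.0}

    rows: list[dict[str, Any]] = []
    for i in range(cfg.n_cats):
        cat = f"cat{i + 1}"
        u_cat = rng.normal(0.0, cfg.sigma_cat)
        sess_counter = 0
        for dose in doses:
            d = dose - DOSE_CENTER
            fixed = cfg.beta0 + b1 * d + b2 * d * d
            for _ in range(cfg.sessions_per_dose):
                sess_counter += 1
                session = f"s{sess_counter}"
                u_sess = rng.normal(0.0, cfg.sigma_session)
                for cortex, off in offsets.items():
                    for k in range(cfg.epochs_per_condition):
                        stim = include_stim and (k % 2 == 1)
                        eps = rng.normal(0.0, cfg.sigma_eps)
                        c_val = (
                            fixed + off + (cfg.stim_effect if stim else 0.0)
                            + u_cat + u_sess + eps
                        )
                        row = {
                            "cat": cat, "session": session, "dose": dose,
                            "stim": bool(stim), "epoch": k, "C": c_val,
                        }
                        if cortex_offsets is not None:
                            row["cortex"] = cortex
                        rows.append(row)
    return pd.DataFrame(rows)
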