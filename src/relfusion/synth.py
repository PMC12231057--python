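"""Synthetic Latin Square Task data with the statistical structure the
analysis assumes.

The generator emulates the two study arms (an fMRI arm, n = 40, and an EEG
arm, n = 45) of a 36-puzzle experiment: 12 unique puzzle designs at each of
three relational-complexity levels, each presented as several rotated
replicates.  Three coupled outputs are produced:

* behaviour — per-participant, per-puzzle accuracy (rotation-level Bernoulli
  outcomes averaged into a proportion) and response time, calibrated so the
  expected condition means equal the configured targets (defaults are the
  observed study means);
* fMRI — region-wise puzzle x feature beta patterns whose pairwise squared
  distances mix relational-complexity (RC) and cognitive-effort (CE)
  geometry, implanted through classical MDS embeddings of the model RDMs so
  the implanted distances reproduce the model distances exactly before noise;
* EEG — sensor epochs (-0.4 to 4.5 s at 250 Hz, 1225 samples) of 1/f
  background noise plus band-limited alpha/beta oscillations whose
  across-puzzle sensor geometry matches the RC model, amplitude-ramped inside
  a late 2.5-4.1 s window and zero outside.

Every output is a pure function of ``GeneratorConfig.seed``; independent
substreams (puzzle difficulty, each modality, each participant) are derived
from the seed with fixed integer tags so modalities can be regenerated
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .containers import BANDS, EegDataset, FmriDataset
from .models import build_ce_model, build_rc_model
from .puzzles import PuzzleSet, make_puzzle_set

# substream tags for seed derivation (default_rng([seed, TAG, ...]))
_TAG_PUZZLE = 10
_TAG_BEHAVIOUR = {"fmri": 1, "eeg": 2}
_TAG_FMRI = 3
_TAG_EEG = 4
_TAG_MIXING = 20

#: 13 functional networks (Ji et al. style cortical networks + subcortex).
NETWORKS = (
    "auditory",
    "cingulo-opercular",
    "default",
    "dorsal-attention",
    "frontoparietal",
    "language",
    "orbito-affective",
    "posterior-multimodal",
    "somatomotor",
    "subcortical",
    "ventral-multimodal",
    "visual1",
    "visual2",
)

# region counts per network at the default 376-region parcellation
# (360 cortical + 16 subcortical), loosely mirroring published network sizes
_NETWORK_WEIGHTS = {
    "visual1": 6,
    "visual2": 54,
    "somatomotor": 39,
    "cingulo-opercular": 56,
    "dorsal-attention": 23,
    "language": 23,
    "frontoparietal": 50,
    "auditory": 15,
    "default": 68,
    "posterior-multimodal": 14,
    "ventral-multimodal": 6,
    "orbito-affective": 6,
    "subcortical": 16,
}

# geometry-implant magnitudes per network: strongest in the higher-order
# control networks, absent in orbito-affective (a designed null network)
_DEFAULT_RC_EFFECT = {
    "frontoparietal": 1.0,
    "dorsal-attention": 1.0,
    "cingulo-opercular": 1.0,
    "visual1": 0.6,
    "visual2": 0.6,
    "default": 0.6,
    "language": 0.6,
    "posterior-multimodal": 0.6,
    "somatomotor": 0.35,
    "auditory": 0.35,
    "ventral-multimodal": 0.35,
    "subcortical": 0.35,
    "orbito-affective": 0.0,
}
_DEFAULT_CE_EFFECT = {
    net: (0.4 if v >= 1.0 else 0.25 if v >= 0.6 else 0.1 if v > 0 else 0.0)
    for net, v in _DEFAULT_RC_EFFECT.items()
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study.

    Condition means default to the observed study values; dispersions and
    signal-to-noise settings are the generator's own model of trial-level
    variability (the study does not report them).
    """

    seed: int = 0

    # behaviour calibration (Binary, Ternary, Quaternary)
    acc_means_fmri: tuple = (0.9666, 0.8702, 0.6625)
    acc_means_eeg: tuple = (0.9500, 0.8069, 0.5630)
    rt_means_fmri: tuple = (0.74, 0.81, 0.93)   # seconds
    rt_means_eeg: tuple = (0.61, 0.78, 0.87)
    n_participants_fmri: int = 40
    n_participants_eeg: int = 45
    n_rotations_fmri: int = 3
    n_rotations_eeg: int = 4

    # behavioural dispersion (logit scale for accuracy, log scale for RT)
    puzzle_acc_sd: float = 0.35
    participant_acc_sd: float = 0.20
    puzzle_rt_sd: float = 0.06
    participant_rt_sd: float = 0.08
    trial_rt_sd: float = 0.10
    sample_trials: bool = True

    # fMRI patterns
    n_regions: int = 376
    n_features: int = 30
    fmri_noise_sd: float = 1.0
    rc_effect: dict = field(default_factory=lambda: dict(_DEFAULT_RC_EFFECT))
    ce_effect: dict = field(default_factory=lambda: dict(_DEFAULT_CE_EFFECT))

    # EEG epochs
    n_sensors: int = 64
    sample_rate: float = 250.0
    t_start: float = -0.4
    t_end: float = 4.5
    implant_window: tuple = (2.5, 4.1)
    implant_bands: tuple = ("alpha", "beta")
    rc_amplitude: float = 5.0        # uV per unit embedding coordinate
    one_over_f_exponent: float = 1.0
    eeg_noise_sd: float = 10.0       # broadband background sd, uV

    def __post_init__(self):
        for arm in ("fmri", "eeg"):
            means = getattr(self, f"acc_means_{arm}")
            if any(not (0.0 <= m <= 1.0) for m in means):
                raise ValueError(f"accuracy means must lie in [0, 1]: {means}")
            rts = getattr(self, f"rt_means_{arm}")
            if any(m <= 0 for m in rts):
                raise ValueError(f"RT means must be positive: {rts}")
        if any(v < 0 for v in self.rc_effect.values()):
            raise ValueError("rc_effect magnitudes must be non-negative")
        if any(v < 0 for v in self.ce_effect.values()):
            raise ValueError("ce_effect magnitudes must be non-negative")
        w0, w1 = self.implant_window
        if not (self.t_start <= w0 < w1 <= self.t_end):
            raise ValueError("implant_window must lie within the epoch")
        unknown = set(self.implant_bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown implant bands: {sorted(unknown)}")

    def puzzle_set(self, arm: str = "fmri") -> PuzzleSet:
        n_rot = self.n_rotations_fmri if arm == "fmri" else self.n_rotations_eeg
        return make_puzzle_set(12, 3, n_rot, seed=self.seed)


def _rng(cfg: GeneratorConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed)] + [int(t) for t in tags])


def _arm_params(cfg: GeneratorConfig, arm: str):
    if arm not in ("fmri", "eeg"):
        raise ValueError(f"arm must be 'fmri' or 'eeg', got {arm!r}")
    return (
        np.asarray(getattr(cfg, f"acc_means_{arm}"), dtype=float),
        np.asarray(getattr(cfg, f"rt_means_{arm}"), dtype=float),
        getattr(cfg, f"n_participants_{arm}"),
        getattr(cfg, f"n_rotations_{arm}"),
    )


def _puzzle_difficulty(cfg: GeneratorConfig, n_puzzles: int):
    """Per-puzzle difficulty offsets, shared across the two study arms so the
    same puzzles are relatively hard in both (as observed empirically)."""
    rng = _rng(cfg, _TAG_PUZZLE)
    d_acc = rng.normal(0.0, 1.0, n_puzzles)
    d_rt = rng.normal(0.0, 1.0, n_puzzles)
    # harder puzzles (lower accuracy) also tend to be slower
    d_rt = 0.6 * d_acc + 0.8 * d_rt
    return d_acc, d_rt


def simulate_behaviour(puzzles: PuzzleSet, cfg: GeneratorConfig,
                       arm: str = "fmri") -> pd.DataFrame:
    """Per-participant, per-puzzle accuracy and response time.

    Success probabilities are the condition means perturbed on the logit
    scale by shared puzzle-difficulty and participant offsets, then
    re-centred within condition so the expected condition mean equals the
    configured target.  Accuracy is the mean of rotation-level Bernoulli
    outcomes (a proportion); RT is log-normal around the condition mean.
    With all dispersions zero and ``sample_trials=False`` the outputs equal
    the configured means exactly.
    """
    acc_means, rt_means, n_part, n_rot = _arm_params(cfg, arm)
    lev = np.asarray(puzzles.complexity)
    if lev.max() > acc_means.size:
        raise ValueError("more complexity levels than configured means")
    n_puz = puzzles.n_puzzles
    rng = _rng(cfg, _TAG_BEHAVIOUR[arm])
    d_acc, d_rt = _puzzle_difficulty(cfg, n_puz)

    p_target = acc_means[lev - 1]
    logit = np.log(np.clip(p_target, 1e-12, 1 - 1e-12) /
                   np.clip(1 - p_target, 1e-12, 1.0))
    u_part = rng.normal(0.0, cfg.participant_acc_sd, n_part)
    m = logit[None, :] - cfg.puzzle_acc_sd * d_acc[None, :] + u_part[:, None]
    p = 1.0 / (1.0 + np.exp(-m))
    for c in np.unique(lev):
        sel = lev == c
        p[:, sel] += acc_means[c - 1] - p[:, sel].mean()
    p = np.clip(p, 0.0, 1.0)
    if cfg.sample_trials:
        acc = rng.binomial(n_rot, p) / float(n_rot)
    else:
        acc = p

    rt_target = rt_means[lev - 1]
    v_part = rng.normal(0.0, cfg.participant_rt_sd, n_part)
    noise = rng.normal(0.0, cfg.trial_rt_sd, (n_part, n_puz))
    rt = rt_target[None, :] * np.exp(
        cfg.puzzle_rt_sd * d_rt[None, :] + v_part[:, None] + noise
    )
    for c in np.unique(lev):
        sel = lev == c
        rt[:, sel] *= rt_means[c - 1] / rt[:, sel].mean()

    part_ids = np.arange(1, n_part + 1)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(part_ids, n_puz),
            "puzzle_id": np.tile(puzzles.puzzle_id, n_part),
            "complexity": np.tile(lev, n_part),
            "accuracy": acc.ravel(),
            "rt": rt.ravel(),
        }
    )


def mds_embedding(dissimilarity: np.ndarray, n_components: int | None = None
                  ) -> np.ndarray:
    """Classical (Torgerson) MDS of a matrix of squared distances.

    Returns an (n, k) coordinate matrix whose pairwise squared Euclidean
    distances reproduce the input exactly when the input is Euclidean-
    embeddable (negative eigenvalues are discarded).
    """
    d2 = np.asarray(dissimilarity, dtype=float)
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, V = eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > max(1e-12, 1e-10 * abs(w[0]))
    X = V[:, keep] * np.sqrt(w[keep])
    if n_components is not None:
        X = X[:, :n_components]
    return X


def make_parcellation(n_regions: int = 376) -> dict:
    """Deterministic region -> network map.

    Regions are allotted to the 13 networks proportionally to the default
    376-region weights, with at least one region per network.
    """
    if n_regions < len(NETWORKS):
        raise ValueError(f"need at least {len(NETWORKS)} regions")
    total = sum(_NETWORK_WEIGHTS.values())
    counts = {net: max(1, int(round(_NETWORK_WEIGHTS[net] * n_regions / total)))
              for net in NETWORKS}
    # absorb rounding drift into the largest networks, never below 1 region
    drift = n_regions - sum(counts.values())
    by_size = sorted(NETWORKS, key=lambda n: -counts[n])
    i = 0
    while drift != 0:
        net = by_size[i % len(by_size)]
        step = 1 if drift > 0 else -1
        if counts[net] + step >= 1:
            counts[net] += step
            drift -= step
        i += 1
    out = {}
    rid = 1
    for net in NETWORKS:
        for _ in range(counts[net]):
            out[rid] = net
            rid += 1
    return out


def _orthonormal_rows(rng: np.random.Generator, d: int, m: int) -> np.ndarray:
    """A (d, m) matrix with orthonormal rows (d <= m), so right-multiplying an
    embedding by it preserves all pairwise distances."""
    if d > m:
        raise ValueError("cannot embed into fewer dimensions than the code")
    q, _ = np.linalg.qr(rng.standard_normal((m, d)))
    return q[:, :d].T


def _check_behaviour_covers(puzzles: PuzzleSet, behaviour: pd.DataFrame):
    have = set(behaviour["puzzle_id"].unique())
    need = set(int(p) for p in puzzles.puzzle_id)
    if not need <= have:
        raise ValueError(
            f"behaviour table missing puzzles {sorted(need - have)[:5]}..."
        )


def simulate_fmri_patterns(puzzles: PuzzleSet, behaviour: pd.DataFrame,
                           cfg: GeneratorConfig,
                           participants=None) -> list[FmriDataset]:
    """Region-wise beta patterns for the fMRI arm.

    Each region's rotation-level pattern is
    ``rc_effect(network) * RC_embedding + ce_effect(network) * CE_embedding
    + iid noise``, where the embeddings are classical-MDS codes of the model
    RDMs mapped into feature space through region-specific orthonormal
    mixing (distance-preserving).  Rotation replicates are independent noisy
    re-draws; averaging them back to one row per puzzle happens downstream.

    ``participants`` selects a subset of 1-based participant ids; each
    participant's data depend only on (seed, participant), so subsets are
    reproducible independently of the rest of the group.
    """
    _check_behaviour_covers(puzzles, behaviour)
    if participants is None:
        participants = range(1, cfg.n_participants_fmri + 1)
    n_rot = cfg.n_rotations_fmri
    n_puz = puzzles.n_puzzles
    rc = build_rc_model(puzzles)
    ce = build_ce_model(behaviour)
    e_rc = mds_embedding(rc.values)
    e_ce = mds_embedding(ce.values, n_components=cfg.n_features)
    region_to_network = make_parcellation(cfg.n_regions)

    # stable per-region mixing, shared across participants
    mix_rng = _rng(cfg, _TAG_MIXING, _TAG_FMRI)
    mixes = {}
    for rid in range(1, cfg.n_regions + 1):
        q1 = _orthonormal_rows(mix_rng, e_rc.shape[1], cfg.n_features)
        q2 = _orthonormal_rows(mix_rng, e_ce.shape[1], cfg.n_features)
        mixes[rid] = (q1, q2)

    row_puzzle_ids = np.tile(puzzles.puzzle_id, n_rot)
    out = []
    for pid in participants:
        rng = _rng(cfg, _TAG_FMRI, pid)
        patterns = {}
        for rid in range(1, cfg.n_regions + 1):
            net = region_to_network[rid]
            q1, q2 = mixes[rid]
            base = (cfg.rc_effect.get(net, 0.0) * (e_rc @ q1)
                    + cfg.ce_effect.get(net, 0.0) * (e_ce @ q2))
            noise = rng.normal(0.0, cfg.fmri_noise_sd,
                               (n_rot, n_puz, cfg.n_features))
            rows = (base[None, :, :] + noise).reshape(-1, cfg.n_features)
            patterns[rid] = rows
        out.append(FmriDataset(pid, patterns, row_puzzle_ids,
                               dict(region_to_network)))
    return out


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                      fs: float, exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with a power-law (1/f^exponent) power spectrum."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    scale = sd / shaped.std()
    return shaped * scale


def simulate_eeg_epochs(puzzles: PuzzleSet, behaviour: pd.DataFrame,
                        cfg: GeneratorConfig,
                        participants=None) -> list[EegDataset]:
    """Sensor-level epochs for the EEG arm.

    Epochs are 1/f background noise plus band-limited sinusoidal carriers
    (one per implant band, random phase per participant) whose across-puzzle
    sensor geometry equals the RC model RDM, Hann-ramped inside the implant
    window and exactly zero outside it.
    """
    _check_behaviour_covers(puzzles, behaviour)
    if participants is None:
        participants = range(1, cfg.n_participants_eeg + 1)
    n_samp = int(round((cfg.t_end - cfg.t_start) * cfg.sample_rate))
    times = cfg.t_start + np.arange(n_samp) / cfg.sample_rate
    n_puz = puzzles.n_puzzles

    rc = build_rc_model(puzzles)
    e_rc = mds_embedding(rc.values)
    if e_rc.shape[1] > cfg.n_sensors:
        raise ValueError("more embedding dimensions than sensors")
    mix_rng = _rng(cfg, _TAG_MIXING, _TAG_EEG)
    q = _orthonormal_rows(mix_rng, e_rc.shape[1], cfg.n_sensors)
    codes = e_rc @ q  # (n_puzzles, n_sensors); pairwise sq dists = RC model

    w0, w1 = cfg.implant_window
    env = np.zeros(n_samp)
    inside = (times >= w0) & (times <= w1)
    env[inside] = np.sin(np.pi * (times[inside] - w0) / (w1 - w0)) ** 2

    out = []
    for pid in participants:
        rng = _rng(cfg, _TAG_EEG, pid)
        bg = _one_over_f_noise(rng, (n_puz, cfg.n_sensors), n_samp,
                               cfg.sample_rate, cfg.one_over_f_exponent,
                               cfg.eeg_noise_sd)
        carrier = np.zeros(n_samp)
        for band in cfg.implant_bands:
            lo, hi = BANDS[band]
            f_c = 0.5 * (lo + hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            carrier += np.sin(2.0 * np.pi * f_c * times + phase)
        implant = (cfg.rc_amplitude * env * carrier)[None, None, :] \
            * codes[:, :, None]
        out.append(EegDataset(pid, bg + implant, puzzles.puzzle_id,
                              cfg.sample_rate, cfg.t_start, cfg.t_end))
    return out


def scaled_config(cfg: GeneratorConfig, **overrides) -> GeneratorConfig:
    """A copy of ``cfg`` with fields replaced (convenience for reduced-scale
    runs)."""
    return replace(cfg, **overrides)
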