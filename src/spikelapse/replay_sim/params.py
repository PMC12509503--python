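"""Parameter tables for the CA3-CA1 spiking replay model.

Neuron dynamics are adaptive exponential leaky integrate-and-fire (AELIF);
synapses are conductance-based with bi-exponential kinetics; CA3->CA3 and
CA3->CA1 pyramidal weights are learned by STDP during simulated
exploration and then frozen for the offline (replay) state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AelifParams",
    "PYRAMIDAL",
    "INTERNEURON",
    "SynapseSpec",
    "OFFLINE_SYNAPSES",
    "StdpConfig",
    "CA3_CA3_STDP",
    "CA3_CA1_STDP",
    "PlaceFieldMap",
    "IsStimConfig",
    "LfpProxyConfig",
    "NetworkConfig",
]

E_AMPA_MV = 0.0
E_GABA_MV = -90.0


@dataclass(frozen=True)
class AelifParams:
    """Adaptive exponential integrate-and-fire neuron parameters."""

    C_m_pF: float
    g_L_nS: float
    E_L_mV: float
    theta_mV: float          # exponential spike-initiation threshold
    Delta_T_mV: float
    V_peak_mV: float         # spike detected when V crosses this
    V_reset_mV: float
    t_ref_ms: float
    tau_w_ms: float
    a_nS: float
    b_pA: float

    def __post_init__(self) -> None:
        if min(self.C_m_pF, self.g_L_nS, self.tau_w_ms) <= 0 or self.t_ref_ms < 0:
            raise ValueError("C_m, g_L, tau_w must be > 0 and t_ref >= 0")


PYRAMIDAL = AelifParams(
    C_m_pF=180.0, g_L_nS=4.3, E_L_mV=-75.0, theta_mV=-24.0, Delta_T_mV=4.23,
    V_peak_mV=-3.25, V_reset_mV=-29.7, t_ref_ms=5.9, tau_w_ms=83.4,
    a_nS=-0.27, b_pA=206.84,
)
INTERNEURON = AelifParams(
    C_m_pF=118.0, g_L_nS=7.5, E_L_mV=-74.0, theta_mV=-57.7, Delta_T_mV=4.6,
    V_peak_mV=-34.78, V_reset_mV=-65.0, t_ref_ms=1.0, tau_w_ms=178.58,
    a_nS=3.05, b_pA=0.91,
)


@dataclass(frozen=True)
class SynapseSpec:
    """One projection of the offline network."""

    pre: str
    post: str
    weight_nS: float | str      # number, or "STDP" for learned matrices
    delay_ms: float
    rise_ms: float
    decay_ms: float
    p_connect: float
    E_rev_mV: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_connect <= 1):
            raise ValueError("p_connect must be in [0, 1]")
        if self.rise_ms >= self.decay_ms:
            raise ValueError("rise must be shorter than decay")


OFFLINE_SYNAPSES: tuple[SynapseSpec, ...] = (
    SynapseSpec("ca3_pyr", "ca3_pyr", "STDP", 1.0, 1.0, 9.0, 0.1, E_AMPA_MV),
    SynapseSpec("ca3_pyr", "ca1_pyr", "STDP", 1.0, 1.0, 9.0, 0.1, E_AMPA_MV),
    SynapseSpec("ca3_pyr", "ca3_int", 0.85, 1.0, 1.0, 9.0, 0.1, E_AMPA_MV),
    SynapseSpec("ca1_pyr", "ca1_int", 0.85, 1.0, 1.0, 9.0, 0.1, E_AMPA_MV),
    # Feedback inhibition carries the strong GABA weight: with the weak
    # weight onto pyramidal cells the recurrent excitation either fails to
    # ignite or never terminates, and the discrete sharp-wave-like bursts
    # this model exists to produce do not occur.
    SynapseSpec("ca3_int", "ca3_pyr", 5.0, 1.0, 0.3, 3.0, 0.25, E_GABA_MV),
    SynapseSpec("ca1_int", "ca1_pyr", 5.0, 1.0, 0.3, 3.0, 0.25, E_GABA_MV),
    SynapseSpec("ca3_int", "ca3_int", 0.65, 1.0, 0.3, 3.0, 0.25, E_GABA_MV),
    SynapseSpec("ca1_int", "ca1_int", 0.65, 1.0, 0.3, 3.0, 0.25, E_GABA_MV),
)

# Dentate background drive: a single pooled Poisson source.
DG_RATE_HZ = 12.0
DG_WEIGHT_SPONTANEOUS_NS = 15.0
DG_WEIGHT_CUED_NS = 10.0
DG_RISE_MS, DG_DECAY_MS, DG_DELAY_MS, DG_P_CONNECT = 0.65, 5.4, 1.0, 0.25

CUE_WEIGHT_NS = 80.0
CUE_RATE_HZ = 30.0
CUE_DURATION_MS = 20.0
CUE_WINDOW_CM = 20.0


@dataclass(frozen=True)
class StdpConfig:
    """Pair-based STDP on normalized weights w in [0, 1].

    dw = lambda_step * (1 - w)^mu_plus * exp(-dt / tau_plus)   for dt > 0
    dw = -lambda_step * alpha * w^mu_minus * exp(-|dt| / tau_minus) for dt <= 0

    with mu = 0 the updates are weight independent; alpha = -1 makes the
    negative-lag branch facilitating (symmetric rule).
    """

    lambda_step: float
    alpha: float
    tau_plus_ms: float
    tau_minus_ms: float
    w_max_nS: float
    mu_plus: float = 0.0
    mu_minus: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_plus_ms <= 0 or self.tau_minus_ms <= 0:
            raise ValueError("STDP time constants must be > 0")


CA3_CA3_STDP = StdpConfig(lambda_step=0.08, alpha=-1.0, tau_plus_ms=62.5,
                          tau_minus_ms=62.5, w_max_nS=40.0)
CA3_CA1_STDP = StdpConfig(lambda_step=0.8, alpha=0.4, tau_plus_ms=20.0,
                          tau_minus_ms=40.0, w_max_nS=40.0)


@dataclass
class PlaceFieldMap:
    """Place-field assignment for one pyramidal population.

    ``centers_cm`` is nan for non-place cells.  The virtual maze is two
    arms of ``half_track_cm`` pointing left (negative x) and right.
    """

    centers_cm: np.ndarray
    half_track_cm: float = 150.0
    lambda_max_hz: float = 20.0
    sigma_cm: float = 7.0
    f_theta_hz: float = 7.0
    baseline_hz: float = 0.1
    place_fraction: float = 0.3

    @classmethod
    def random(cls, n_cells: int, rng: np.random.Generator,
               half_track_cm: float = 150.0, place_fraction: float = 0.3,
               **kwargs) -> "PlaceFieldMap":
        centers = np.full(n_cells, np.nan)
        n_place = int(round(place_fraction * n_cells))
        which = rng.choice(n_cells, size=n_place, replace=False)
        centers[which] = rng.uniform(-half_track_cm, half_track_cm, n_place)
        return cls(centers_cm=centers, half_track_cm=half_track_cm,
                   place_fraction=place_fraction, **kwargs)

    @property
    def is_place(self) -> np.ndarray:
        return ~np.isnan(self.centers_cm)


@dataclass(frozen=True)
class IsStimConfig:
    """Interictal-like input delivered to CA3 during exploration.

    ``clustered`` fixes the IS location at +/-100 cm (the reference
    point); ``dispersed`` draws it uniformly along the traversed arm on
    each trial; ``off`` delivers nothing.  A single spike train is drawn
    from the location-locked rate profile and each eligible neuron
    receives each spike with an independent probability.
    """

    mode: str = "off"                  # off | clustered | dispersed
    lambda_max_hz: float = 2000.0
    sigma_cm: float = 4.0
    reference_cm: float = 100.0
    p_deliver: float = 0.01
    delivery: str = "active_place"     # active_place | broadcast
    active_threshold: float = 0.1      # fraction of the spatial envelope peak

    def __post_init__(self) -> None:
        if self.mode not in ("off", "clustered", "dispersed"):
            raise ValueError("mode must be off, clustered or dispersed")
        if not (0 <= self.p_deliver <= 1):
            raise ValueError("p_deliver must be in [0, 1]")


@dataclass(frozen=True)
class LfpProxyConfig:
    """Extracellular proxy: summed synaptic currents of sampled CA1 cells."""

    n_sampled_cells: int = 200
    sigma_ext_S_per_m: float = 0.3
    r_um: float = 5.0
    fs_hz: float = 1000.0


@dataclass
class NetworkConfig:
    """Population sizes and the desk-scale factor.

    ``scale`` shrinks every population together.  Two compensations are
    available for sub-full-size networks:

    * ``"indegree"`` (default): connection probabilities are divided by
      ``scale`` (capped at 1) so every neuron keeps its full-size number
      of inputs at the printed per-synapse conductances.  This preserves
      both the mean input and the connectivity of the STDP-potentiated
      place-field chains that replay propagates along.
    * ``"weight"``: probabilities stay as printed and per-synapse
      conductances are multiplied by 1/scale.  Mean input is preserved
      but the learned chain graph thins with the population and stops
      percolating at small sizes.
    """

    scale: float = 1.0
    scale_mode: str = "indegree"
    n_pyr_ref: int = 1250
    n_int_ref: int = 100
    dt_ms: float = 0.1
    lfp: LfpProxyConfig = field(default_factory=LfpProxyConfig)

    def __post_init__(self) -> None:
        if self.scale_mode not in ("indegree", "weight"):
            raise ValueError("scale_mode must be 'indegree' or 'weight'")

    @property
    def n_pyr(self) -> int:
        return max(2, int(round(self.n_pyr_ref * self.scale)))

    @property
    def n_int(self) -> int:
        return max(1, int(round(self.n_int_ref * self.scale)))

    @property
    def weight_scale(self) -> float:
        return 1.0 / self.scale if self.scale_mode == "weight" else 1.0

    def conn_p(self, p: float) -> float:
        return p if self.scale_mode == "weight" else min(1.0, p / self.scale)
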