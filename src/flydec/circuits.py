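"""Assembly of the linear (central-complex) and nonlinear (mushroom-body)
decision circuits.

The model keeps a single learned memory: the feed-forward weight matrix from
the five input channels to the two behaviour neurons.  Training updates it
once and the same matrix serves as the CC input->output connection of the
linear pathway and the KC->MBON connection of the nonlinear pathway (the two
copies are stored separately so their agreement can be checked, but they
always receive identical updates).

Fixed connection magnitudes (mutual inhibition, the KC/APL/DA loop, the
visual relay and the input-current gain) are calibration parameters: the
wiring and signs are anatomically constrained, the magnitudes are chosen so
the conditioning, colour-intensity-threshold and conflict-amplification
behaviours emerge, and are exposed in the configuration.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .snn_core import (
    EXCITATORY,
    INHIBITORY,
    LIFConfig,
    Network,
    NeuronPopulation,
    STDPConfig,
    SynapseGroup,
)

__all__ = [
    "WeightConfig",
    "DAConfig",
    "ProtocolConfig",
    "ModelConfig",
    "Model",
    "build_model",
    "set_nonlinear_gating",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for malformed configuration input."""


@dataclass(frozen=True)
class WeightConfig:
    """Connection magnitudes (arbitrary units, non-negative).

    ``init_plastic`` seeds every plastic feed-forward weight so the
    untrained model is symmetric between the two behaviours.  ``visual_cc``
    is the fixed one-to-one relay from the visual layer into the CC input
    layer (2.0 makes a single presynaptic spike cross threshold, so the CC
    input layer reproduces the visual spike trains).  The KC/APL/DA-loop
    magnitudes shape the gain-gating competition of the nonlinear pathway.
    """

    init_plastic: float = 0.5
    visual_cc: float = 2.0
    visual_kc: float = 0.5
    mutual_inh: float = 2.0
    kc_apl: float = 3.0
    apl_kc: float = 1.5
    da_apl: float = 3.0
    apl_da: float = 1.5
    da_mbon: float = 0.5
    w_min: float = 0.0
    w_max: float = 10.0
    visual_kc_max: float = 2.0   # upper bound for the visual->KC gate
    soft_gating: bool = False    # multiplicative STDP bounds on gating links
    mbon_gain: float = 0.15      # KC->MBON synaptic efficacy in the choice
                                 # phase (MBONs integrate several KC spikes)


@dataclass(frozen=True)
class DAConfig:
    """Phasic dopamine trace: peak concentration and decay constant (ms)."""

    peak: float = 10.0
    tau_t: float = 2.0
    cutoff_frac: float = 0.01  # trace considered extinguished below this


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing of the training and choice protocols (ms)."""

    train_duration: float = 1000.0
    dt_train: float = 1.0
    exploration_drive: float = 0.12  # tonic current into the behaviour layer
                                     # during training (spontaneous action)
    switch_inhibition: float = 30.0  # clamp on the suppressed behaviour
                                     # neuron; exceeds the maximum
                                     # feed-forward drive so the clamped
                                     # action is really not expressed
    choice_duration: float = 2000.0
    subtrial: float = 100.0
    dt_choice: float = 0.1
    da_duration: float = 100.0  # external DA activation at choice onset
    da_drive: float = 3.0       # external current into the DA neuron
    apl_drive: float = 0.15     # tonic current into the APL interneurons
    gate_window: float = 500.0  # spike-count window for gain-gating readouts
    input_gain: float = 0.105   # current per unit channel saliency


@dataclass(frozen=True)
class ModelConfig:
    lif: LIFConfig = field(default_factory=LIFConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    weights: WeightConfig = field(default_factory=WeightConfig)
    da: DAConfig = field(default_factory=DAConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    th: float = 3.0  # conflict-monitor threshold

    def to_dict(self) -> dict:
        return {
            "lif": asdict(self.lif),
            "stdp": asdict(self.stdp),
            "weights": asdict(self.weights),
            "da": asdict(self.da),
            "protocol": asdict(self.protocol),
            "th": self.th,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        sections = {
            "lif": LIFConfig,
            "stdp": STDPConfig,
            "weights": WeightConfig,
            "da": DAConfig,
            "protocol": ProtocolConfig,
        }
        kwargs: dict = {}
        unknown = set(data) - set(sections) - {"th"}
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        for name, typ in sections.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            bad = set(section) - {f for f in typ.__dataclass_fields__}
            if bad:
                raise ConfigError(
                    f"unknown keys in config section {name!r}: {sorted(bad)}"
                )
            kwargs[name] = typ(**section)
        if "th" in data:
            kwargs["th"] = float(data["th"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def _eye_mask(n: int) -> np.ndarray:
    return np.eye(n)


def _offdiag_mask(n: int) -> np.ndarray:
    return 1.0 - np.eye(n)


class Model:
    """The assembled two-pathway decision model.

    Holds the configuration, the learned feed-forward memory (two copies:
    ``W_cc`` for the linear pathway, ``W_mb`` for the nonlinear pathway,
    kept identical by the training rules) and the DA/APL gating switches
    used for ablation variants.
    """

    N_BEHAVIOR = 2
    N_APL = 2

    def __init__(self, config: ModelConfig, n_channels: int = 5, seed: int = 0):
        if n_channels < 1:
            raise ConfigError("n_channels must be positive")
        if config.th <= 0:
            raise ConfigError("conflict threshold must be positive")
        self.config = config
        self.n_channels = n_channels
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        w = config.weights
        init = np.full((n_channels, self.N_BEHAVIOR), w.init_plastic)
        self.W_cc = init.copy()
        self.W_mb = init.copy()
        self.da_on = True
        self.apl_on = True

    # -- phase network builders -------------------------------------------

    def _behavior_pop(self, label: str) -> NeuronPopulation:
        return NeuronPopulation(label, self.N_BEHAVIOR, tie_break=True)

    def training_network(self) -> tuple[Network, SynapseGroup]:
        """Visual -> CC-input relay -> behaviour layer with plastic
        feed-forward weights and mutual inhibition.

        Training is identical for the linear and nonlinear pathways, so a
        single feed-forward learner is simulated; the caller writes the
        learned matrix back to both ``W_cc`` and ``W_mb``.
        """
        cfg = self.config
        w = cfg.weights
        net = Network(lif=cfg.lif)
        visual = net.add_population(NeuronPopulation("visual", self.n_channels))
        cc_in = net.add_population(NeuronPopulation("cc_input", self.n_channels))
        out = net.add_population(self._behavior_pop("output"))
        net.connect(SynapseGroup(
            visual, cc_in, w.visual_cc, mask=_eye_mask(self.n_channels),
            w_max=w.w_max,
        ))
        ff = net.connect(SynapseGroup(
            cc_in, out, self.W_cc.copy(), plastic=True, stdp=cfg.stdp,
            w_min=w.w_min, w_max=w.w_max,
        ))
        net.connect(SynapseGroup(
            out, out, w.mutual_inh, sign=INHIBITORY,
            mask=_offdiag_mask(self.N_BEHAVIOR),
        ))
        return net, ff

    def linear_network(self) -> tuple[Network, dict[str, SynapseGroup]]:
        """The choice-phase linear pathway; memory weights frozen."""
        cfg = self.config
        w = cfg.weights
        net = Network(lif=cfg.lif)
        visual = net.add_population(NeuronPopulation("visual", self.n_channels))
        cc_in = net.add_population(NeuronPopulation("cc_input", self.n_channels))
        out = net.add_population(self._behavior_pop("output"))
        groups = {}
        net.connect(SynapseGroup(
            visual, cc_in, w.visual_cc, mask=_eye_mask(self.n_channels),
            w_max=w.w_max,
        ))
        groups["ff"] = net.connect(SynapseGroup(
            cc_in, out, self.W_cc.copy(), w_min=w.w_min, w_max=w.w_max,
        ))
        net.connect(SynapseGroup(
            out, out, w.mutual_inh, sign=INHIBITORY,
            mask=_offdiag_mask(self.N_BEHAVIOR),
        ))
        return net, groups

    def nonlinear_network(self) -> tuple[Network, dict[str, SynapseGroup]]:
        """The choice-phase mushroom-body pathway with the DA-APL-KC loop.

        KC->MBON memory is frozen; the gating connections (visual->KC,
        APL->KC, APL->DA, DA->MBON) carry choice-phase STDP.  The gating
        switches ``da_on`` / ``apl_on`` remove the outgoing connections of
        the respective population for ablation variants.
        """
        cfg = self.config
        w = cfg.weights
        net = Network(lif=cfg.lif)
        visual = net.add_population(NeuronPopulation("visual", self.n_channels))
        kc = net.add_population(NeuronPopulation("kc", self.n_channels))
        mbon = net.add_population(self._behavior_pop("output"))
        apl = net.add_population(NeuronPopulation("apl", self.N_APL))
        # APL inhibition is tonic: without dopamine suppression the
        # interneurons fire even before Kenyon-cell feedback arrives
        apl.i_ext[:] = cfg.protocol.apl_drive
        da = net.add_population(NeuronPopulation("da", 1))
        groups = {}
        groups["visual_kc"] = net.connect(SynapseGroup(
            visual, kc, w.visual_kc, mask=_eye_mask(self.n_channels),
            plastic=True, stdp=cfg.stdp, w_min=w.w_min, w_max=w.visual_kc_max,
            soft_bounds=w.soft_gating,
        ))
        groups["ff"] = net.connect(SynapseGroup(
            kc, mbon, self.W_mb * w.mbon_gain, w_min=w.w_min, w_max=w.w_max,
        ))
        net.connect(SynapseGroup(
            mbon, mbon, w.mutual_inh, sign=INHIBITORY,
            mask=_offdiag_mask(self.N_BEHAVIOR),
        ))
        net.connect(SynapseGroup(kc, apl, w.kc_apl, w_max=w.w_max))
        if self.apl_on:
            groups["apl_kc"] = net.connect(SynapseGroup(
                apl, kc, w.apl_kc, sign=INHIBITORY, plastic=True,
                stdp=cfg.stdp, w_min=w.w_min, w_max=w.w_max,
                soft_bounds=w.soft_gating,
            ))
            groups["apl_da"] = net.connect(SynapseGroup(
                apl, da, w.apl_da, sign=INHIBITORY, plastic=True,
                stdp=cfg.stdp, w_min=w.w_min, w_max=w.w_max,
                soft_bounds=w.soft_gating,
            ))
        if self.da_on:
            net.connect(SynapseGroup(da, apl, w.da_apl, sign=INHIBITORY))
            groups["da_mbon"] = net.connect(SynapseGroup(
                da, mbon, w.da_mbon, plastic=True, stdp=cfg.stdp,
                w_min=w.w_min, w_max=w.w_max, soft_bounds=w.soft_gating,
            ))
        return net, groups

    # -- conflict monitor ---------------------------------------------------

    def monitor_sums(self, filtered_input: np.ndarray) -> tuple[float, float]:
        """Summed CC memory weights from active input channels to each
        behaviour neuron."""
        active = np.asarray(filtered_input, dtype=float) > 0
        s1 = float(self.W_cc[active, 0].sum())
        s2 = float(self.W_cc[active, 1].sum())
        return s1, s2

    def copy(self) -> "Model":
        dup = Model(self.config, self.n_channels, self.seed)
        dup.W_cc = self.W_cc.copy()
        dup.W_mb = self.W_mb.copy()
        dup.da_on = self.da_on
        dup.apl_on = self.apl_on
        dup.rng = copy.deepcopy(self.rng)
        return dup


def build_model(
    config: ModelConfig | dict | None = None,
    n_channels: int = 5,
    seed: int = 0,
) -> Model:
    """Build an untrained model from a configuration.

    The untrained model is symmetric between the two behaviours: every
    plastic feed-forward weight is equal and the mutual-inhibition weights
    are equal, so repeated untrained choice trials split evenly.
    """
    if config is None:
        config = ModelConfig()
    elif isinstance(config, dict):
        config = ModelConfig.from_dict(config)
    return Model(config, n_channels=n_channels, seed=seed)


def set_nonlinear_gating(model: Model, da_on: bool, apl_on: bool) -> Model:
    """Return a model variant with DA and/or APL outgoing connections
    removed (ablation experiments).  ``(False, False)`` reduces the
    nonlinear pathway to the plain feed-forward KC->MBON pass."""
    variant = model.copy()
    variant.da_on = bool(da_on)
    variant.apl_on = bool(apl_on)
    return variant
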