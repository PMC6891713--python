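"""Deployment emulation: precision conversion, arithmetic cost, battery life.

Porting a trained model to a microcontroller changes its numerics; here the
conversion toolchain is emulated by precision reduction (float64 -> float32,
or fixed-point quantize-dequantize of weights and activations) and assessed
by the relative L2 error between the flattened softmax outputs of the two
model versions,

    e = ||F_generated - F_original|| / ||F_generated||,

with the *generated* (converted) model in the denominator.  Compute cost is
an exact multiply-accumulate (MAC) count per block inference; energy is a
duty-cycle battery model: hours = capacity / average current, with the
average over continuous tasks (duty x current), the stop-mode remainder,
and per-event transmission charges.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .rnncore import GRUParams, LSTMParams, ModelParams
from .synthdata import CLASSES

logger = logging.getLogger(__name__)

# Default currents (mA) and battery from the emulated hardware: ADXL345
# accelerometer read over I2C, HC-06 Bluetooth transmit, STM32 stop mode.
READ_CURRENT_MA = 5.0
TRANSFORM_CURRENT_MA = 5.0
RNN_CURRENT_MA = 5.0
TRANSMIT_CURRENT_MA = 43.0
STOP_CURRENT_MA = 0.01  # "< 10 uA" taken as a point value
BATTERY_CAPACITY_MAH = 150.0
#: Bluetooth per-transmission duration (13-byte payload at 9600 baud); an
#: overridable assumption — the source hardware figure is not published.
TRANSMIT_DURATION_S = 0.0135
#: Per-sample read/transform durations in the streaming design (assumption).
READ_DURATION_S = 0.0015
TRANSFORM_DURATION_S = 0.0015

#: Fraction of time the processor runs the model in the on-device design.
ONDEVICE_DUTY = {"1xLSTM": 0.825, "2xLSTM": 0.825, "1xGRU": 0.575, "2xGRU": 0.575}


# ---------------------------------------------------------------------------
# Precision conversion


@dataclass
class QuantizationScheme:
    """Precision-reduction recipe.

    ``float64``: identity (no change).  ``float32``: round every weight to
    IEEE single precision.  ``fixed``: round weights — and, when
    ``quantize_activations``, every intermediate layer output — to a signed
    Q(total_bits, fraction_bits) grid with saturation; accumulators stay at
    full precision.
    """

    mode: str = "float32"  # float64 | float32 | fixed
    total_bits: int = 16
    fraction_bits: int = 8
    rounding: str = "nearest"  # nearest | floor
    quantize_activations: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("float64", "float32", "fixed"):
            raise ValueError(f"unknown quantization mode {self.mode!r}")
        if self.mode == "fixed":
            if self.total_bits not in (8, 16, 32):
                raise ValueError("total_bits must be 8, 16 or 32")
            if not 0 <= self.fraction_bits < self.total_bits:
                raise ValueError("fraction_bits must be < total_bits")
        if self.rounding not in ("nearest", "floor"):
            raise ValueError(f"unknown rounding rule {self.rounding!r}")

    def quantizer(self):
        """Elementwise quantize-dequantize function for this scheme."""
        if self.mode == "float64":
            return lambda a: np.asarray(a, dtype=float)
        if self.mode == "float32":
            return lambda a: np.asarray(a, dtype=float).astype(np.float32).astype(np.float64)
        step = 2.0 ** -self.fraction_bits
        lo = -(2.0 ** (self.total_bits - 1)) * step
        hi = (2.0 ** (self.total_bits - 1) - 1) * step
        rounder = np.round if self.rounding == "nearest" else np.floor

        def q(a, _counter=[0]):
            a = np.asarray(a, dtype=float)
            clipped = np.clip(a, lo, hi)
            n_over = int(np.count_nonzero(clipped != a))
            if n_over:
                logger.warning("fixed-point saturation clipped %d values", n_over)
            return rounder(clipped / step) * step

        return q


def convert(model: ModelParams, scheme: QuantizationScheme) -> ModelParams:
    """Map every weight through the scheme; architecture unchanged.

    For fixed-point schemes with ``quantize_activations`` the returned model
    also quantizes intermediate activations at run time via its
    ``act_quant`` hook.
    """
    q = scheme.quantizer()
    out = copy.deepcopy(model)
    out.batchnorm.gamma = q(out.batchnorm.gamma)
    out.batchnorm.beta = q(out.batchnorm.beta)
    out.batchnorm.running_mean = q(out.batchnorm.running_mean)
    out.batchnorm.running_var = q(out.batchnorm.running_var)
    for layer in out.recurrent_layers:
        for name in (
            layer.param_names()
            + (["wci", "wcf", "wco"] if isinstance(layer, LSTMParams) else [])
        ):
            setattr(layer, name, q(getattr(layer, name)))
    out.dense.W = q(out.dense.W)
    out.dense.b = q(out.dense.b)
    if scheme.mode == "fixed" and scheme.quantize_activations:
        out.act_quant = q
    return out


def l2_relative_error(F_generated, F_original) -> float:
    """||F_generated - F_original|| / ||F_generated||, flattened.

    Asymmetric by construction: the converted model's output sits in the
    denominator.
    """
    g = np.asarray(F_generated, dtype=float).ravel()
    o = np.asarray(F_original, dtype=float).ravel()
    if g.shape != o.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {o.shape}")
    denom = np.linalg.norm(g)
    if denom == 0:
        raise ValueError("generated output has zero norm; relative error undefined")
    return float(np.linalg.norm(g - o) / denom)


# ---------------------------------------------------------------------------
# Arithmetic cost


def mac_count(model: ModelParams, width: int, include_elementwise: bool = True) -> int:
    """Exact multiply-accumulate count for one block inference.

    Per time step a recurrent layer costs 4(NM + N^2) weight MACs for an
    LSTM (plus 3N peephole MACs when enabled) or 3(NM + N^2) for a GRU,
    plus the elementwise gate products (3N either way); batch normalization
    costs one multiply per channel per step and the dense layer C*N at the
    end.  The GRU is always cheaper than the LSTM at equal sizes.
    """
    if width < 1:
        raise ValueError("width must be positive")
    total = len(model.batchnorm.gamma) * width  # batch-norm scaling
    for layer in model.recurrent_layers:
        N, M = layer.n_units, layer.n_inputs
        if isinstance(layer, LSTMParams):
            per_step = 4 * (N * M + N * N)
            if layer.peepholes_enabled:
                per_step += 3 * N
        else:
            per_step = 3 * (N * M + N * N)
        if include_elementwise:
            per_step += 3 * N  # gate products
        total += per_step * width
    total += model.dense.W.size  # C x N
    return int(total)


# ---------------------------------------------------------------------------
# Battery-life model


@dataclass
class PowerTask:
    """One consumer: either a continuous duty fraction or per-event charges."""

    name: str
    current_mA: float
    duty_fraction: float | None = None
    duration_s: float | None = None  # per event
    events_per_hour: float = 0.0

    def __post_init__(self) -> None:
        if self.current_mA < 0:
            raise ValueError("current must be non-negative")
        if self.duty_fraction is not None and not 0 <= self.duty_fraction <= 1:
            raise ValueError("duty_fraction must be in [0, 1]")
        if self.duty_fraction is None and self.duration_s is None:
            raise ValueError(f"task {self.name!r} needs a duty fraction or event charge")

    @property
    def average_current_mA(self) -> float:
        if self.duty_fraction is not None:
            return self.current_mA * self.duty_fraction
        # charge per event (mA*s) times events/h, over one hour
        return self.current_mA * self.duration_s * self.events_per_hour / 3600.0


@dataclass
class PowerScenario:
    tasks: list
    idle_current_mA: float = STOP_CURRENT_MA
    battery_capacity_mAh: float = BATTERY_CAPACITY_MAH

    def __post_init__(self) -> None:
        if not self.battery_capacity_mAh > 0:
            raise ValueError("battery capacity must be positive")
        duty = sum(t.duty_fraction or 0.0 for t in self.tasks)
        if duty > 1 + 1e-9:
            raise ValueError(f"continuous duty fractions sum to {duty:.3f} > 1")

    @property
    def average_current_mA(self) -> float:
        duty = sum(t.duty_fraction or 0.0 for t in self.tasks)
        avg = sum(t.average_current_mA for t in self.tasks)
        return avg + self.idle_current_mA * (1.0 - duty)


def battery_life(scenario: PowerScenario) -> float:
    """Battery life in hours: capacity / average current."""
    avg = scenario.average_current_mA
    if avg <= 0:
        logger.warning("zero average current: battery life unbounded")
        return float("inf")
    return scenario.battery_capacity_mAh / avg


def scenario_streaming(
    rate_hz: float = 25.0,
    read_duration_s: float = READ_DURATION_S,
    transform_duration_s: float = TRANSFORM_DURATION_S,
    transmit_duration_s: float = TRANSMIT_DURATION_S,
    battery_capacity_mAh: float = BATTERY_CAPACITY_MAH,
) -> PowerScenario:
    """Streaming design: every sample is read, transformed and sent over
    Bluetooth to an external device that runs the model."""
    if not rate_hz > 0:
        raise ValueError("sampling rate must be positive")
    duties = {
        "read": rate_hz * read_duration_s,
        "transform": rate_hz * transform_duration_s,
        "transmit": rate_hz * transmit_duration_s,
    }
    if sum(duties.values()) > 1:
        raise ValueError("per-sample task durations exceed the sampling period")
    tasks = [
        PowerTask("read", READ_CURRENT_MA, duty_fraction=duties["read"]),
        PowerTask("transform", TRANSFORM_CURRENT_MA, duty_fraction=duties["transform"]),
        PowerTask("transmit", TRANSMIT_CURRENT_MA, duty_fraction=duties["transmit"]),
    ]
    return PowerScenario(tasks=tasks, battery_capacity_mAh=battery_capacity_mAh)


def scenario_ondevice(
    arch: str,
    duty_fraction: float | None = None,
    events_per_hour: float = 0.0,
    transmit_duration_s: float = TRANSMIT_DURATION_S,
    battery_capacity_mAh: float = BATTERY_CAPACITY_MAH,
) -> PowerScenario:
    """On-device design: the model runs on the microcontroller and only
    alert/fall events are transmitted.

    Default duty fractions (model execution + sensor reading combined):
    82.5% for the LSTM family, 57.5% for the GRU family.
    """
    if arch not in ONDEVICE_DUTY:
        raise ValueError(f"unknown architecture tag {arch!r}")
    duty = ONDEVICE_DUTY[arch] if duty_fraction is None else duty_fraction
    if not 0 <= duty <= 1:
        raise ValueError("duty fraction must be in [0, 1]")
    tasks = [PowerTask("read+rnn", RNN_CURRENT_MA, duty_fraction=duty)]
    if events_per_hour > 0:
        tasks.append(
            PowerTask(
                "alert-transmit",
                TRANSMIT_CURRENT_MA,
                duration_s=transmit_duration_s,
                events_per_hour=events_per_hour,
            )
        )
    return PowerScenario(tasks=tasks, battery_capacity_mAh=battery_capacity_mAh)


def battery_life_curve(arch: str, event_counts) -> list[tuple[float, float]]:
    """(events per hour, battery hours) pairs for the on-device design."""
    return [
        (float(e), battery_life(scenario_ondevice(arch, events_per_hour=float(e))))
        for e in event_counts
    ]
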