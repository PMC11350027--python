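"""Hadamard time-encoding of pCASL sub-boluses.

In time-encoded pCASL the 3.6 s labeling train is split into sub-boluses,
each toggled between label and control across acquisitions according to a
column of a Sylvester-Hadamard matrix.  Decoding the acquired volumes with
the matrix transpose separates the perfusion-weighted signal of every
sub-bolus, each with its own effective post-labeling delay (PLD), from a
single scan.

Conventions used throughout:

* Matrix rows are acquisitions, column 0 is the static (all ``+1``) column,
  columns ``1..n-1`` are sub-boluses ordered earliest-played-first.
* ``+1`` means control state, ``-1`` label state: a sub-bolus in label state
  subtracts its full perfusion-weighted difference ``dM`` from the static
  signal.
* ``decode_scale = 2/order`` so that one decoded value equals one
  control-minus-label difference ``dM``, directly comparable to
  pairwise-subtraction ASL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hadamard as _sylvester

__all__ = ["SubBolusSchedule", "HadamardScheme", "build_scheme", "encode", "decode"]

#: Paper-protocol sub-bolus durations (ms), earliest played first.  The
#: longest block (the "perfusion block") is played first so that its chained
#: PLD is the longest; the train ends 200 ms before readout.
PROTOCOL_LABEL_DURATIONS_MS = (1800, 600, 400, 300, 200, 150, 150)
#: Effective PLD of each sub-bolus (ms): time from the end of that
#: sub-bolus's labeling to readout.
PROTOCOL_PLDS_MS = (2000, 1400, 1000, 700, 500, 350, 200)


@dataclass(frozen=True)
class SubBolusSchedule:
    """Durations and effective PLDs of the labeling sub-boluses.

    Sub-boluses are played back-to-back, so the PLD of sub-bolus ``i``
    equals the PLD of the next sub-bolus plus that sub-bolus's duration
    (chained timing).  Ordering is earliest-played-first.
    """

    label_duration_ms: tuple = field(default=PROTOCOL_LABEL_DURATIONS_MS)
    pld_ms: tuple = field(default=PROTOCOL_PLDS_MS)

    def __post_init__(self):
        ld = tuple(float(x) for x in self.label_duration_ms)
        pld = tuple(float(x) for x in self.pld_ms)
        object.__setattr__(self, "label_duration_ms", ld)
        object.__setattr__(self, "pld_ms", pld)
        if len(ld) != len(pld):
            raise ValueError("label_duration_ms and pld_ms must have equal length")
        if len(ld) == 0:
            raise ValueError("schedule must contain at least one sub-bolus")
        if any(d <= 0 for d in ld) or any(p <= 0 for p in pld):
            raise ValueError("all durations and PLDs must be strictly positive")
        for i in range(len(ld) - 1):
            if abs(pld[i] - (pld[i + 1] + ld[i + 1])) > 1e-9:
                raise ValueError(
                    "chained timing violated at sub-bolus %d: "
                    "pld[i] must equal pld[i+1] + label_duration[i+1]" % i
                )

    @property
    def n_subboluses(self) -> int:
        return len(self.label_duration_ms)

    @property
    def total_label_duration_ms(self) -> float:
        return float(sum(self.label_duration_ms))

    @property
    def label_duration_s(self) -> np.ndarray:
        return np.asarray(self.label_duration_ms) / 1000.0

    @property
    def pld_s(self) -> np.ndarray:
        return np.asarray(self.pld_ms) / 1000.0

    @property
    def readout_time_s(self) -> np.ndarray:
        """Readout time of each sub-bolus measured from the start of its
        own labeling (``ld + pld``, seconds)."""
        return self.label_duration_s + self.pld_s

    def perfusion_block_index(self) -> int:
        """Index of the longest sub-bolus (the single-PLD 'perfusion block')."""
        return int(np.argmax(self.label_duration_ms))

    def to_dict(self) -> dict:
        return {
            "label_duration_ms": list(self.label_duration_ms),
            "pld_ms": list(self.pld_ms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubBolusSchedule":
        return cls(tuple(d["label_duration_ms"]), tuple(d["pld_ms"]))


@dataclass(frozen=True)
class HadamardScheme:
    """Sylvester-Hadamard encoding matrix with its decode normalisation."""

    order: int
    matrix: np.ndarray
    decode_scale: float

    def to_json(self, schedule: SubBolusSchedule | None = None) -> str:
        payload = {
            "order": self.order,
            "matrix": self.matrix.astype(int).tolist(),
            "decode_scale": self.decode_scale,
        }
        if schedule is not None:
            payload["schedule"] = schedule.to_dict()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "HadamardScheme":
        d = json.loads(text)
        return cls(int(d["order"]), np.asarray(d["matrix"], dtype=int),
                   float(d["decode_scale"]))


def build_scheme(n_subboluses: int) -> HadamardScheme:
    """Construct the Sylvester-Hadamard scheme for ``n_subboluses``.

    The matrix order is ``n_subboluses + 1`` and must be a power of two
    (Sylvester construction); the first row and column are all ``+1``.
    """
    if n_subboluses < 1:
        raise ValueError("n_subboluses must be >= 1")
    order = n_subboluses + 1
    if order & (order - 1) != 0:
        supported = [2**k - 1 for k in range(1, 8)]
        raise ValueError(
            "unsupported Hadamard order %d (n_subboluses + 1 must be a power "
            "of two; supported sub-bolus counts: %s)" % (order, supported)
        )
    matrix = _sylvester(order).astype(int)
    return HadamardScheme(order=order, matrix=matrix, decode_scale=2.0 / order)


def _check_scheme(scheme: HadamardScheme) -> None:
    if scheme.matrix.shape != (scheme.order, scheme.order):
        raise ValueError("scheme matrix shape does not match its order")


def encode(static_signal, subbolus_signals, scheme: HadamardScheme) -> np.ndarray:
    """Forward model of the acquisition: mix sub-bolus signals into volumes.

    ``acq[j] = static - sum_k [matrix[j, k+1] == -1] * subbolus_signals[k]``:
    a sub-bolus in label state subtracts its full perfusion-weighted
    difference; in control state it contributes nothing.

    Parameters are broadcast over leading (voxel) axes; the sub-bolus axis
    is the last axis of ``subbolus_signals`` and the acquisition axis is the
    last axis of the result.
    """
    _check_scheme(scheme)
    sig = np.asarray(subbolus_signals, dtype=float)
    if sig.shape[-1] != scheme.order - 1:
        raise ValueError(
            "expected %d sub-bolus signals, got %d"
            % (scheme.order - 1, sig.shape[-1])
        )
    static = np.asarray(static_signal, dtype=float)[..., None]
    label_state = (1 - scheme.matrix[:, 1:]) / 2.0  # rows=acq, cols=subbolus
    return static - sig @ label_state.T


def decode(acquisitions, scheme: HadamardScheme) -> np.ndarray:
    """Separate the per-sub-bolus perfusion-weighted signals.

    ``pw[k] = decode_scale * sum_j matrix[j, k+1] * acq[j]``.  The sign
    convention makes positive perfusion yield positive decoded signal, and
    ``decode(encode(x)) == x`` exactly.  Independent additive noise of SD
    ``s`` per acquisition propagates to decoded SD
    ``s * sqrt(order) * decode_scale``.
    """
    _check_scheme(scheme)
    acq = np.asarray(acquisitions, dtype=float)
    if acq.shape[-1] != scheme.order:
        raise ValueError(
            "expected %d acquisitions, got %d" % (scheme.order, acq.shape[-1])
        )
    return scheme.decode_scale * (acq @ scheme.matrix[:, 1:])
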