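"""Container for a single 20-second elbow-flexion trial.

The UEF test records angular velocity of the forearm and the upper arm
(arm-worn gyroscopes) while the participant flexes and extends the elbow
repetitively at maximal pace for 20 seconds.  Both channels are expressed in
deg/s about the elbow flexion axis, flexion positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRIAL_DURATION_S = 20.0
DEFAULT_SAMPLING_RATE_HZ = 100.0


@dataclass
class MotionTrace:
    """Timestamped forearm / upper-arm angular-velocity channels, one trial.

    Parameters
    ----------
    sampling_rate : float
        Sampling rate in Hz (>= 50 for the UEF protocol).
    time : ndarray
        Sample times in seconds, strictly increasing, uniformly spaced.
    forearm_velocity : ndarray
        Forearm angular velocity, deg/s.
    upperarm_velocity : ndarray
        Upper-arm angular velocity, deg/s (trunk/arm stabilisation channel).
    subject_id : str, optional
        Identifier linking the trace to a cohort row.
    """

    sampling_rate: float
    time: np.ndarray
    forearm_velocity: np.ndarray
    upperarm_velocity: np.ndarray
    subject_id: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.forearm_velocity = np.asarray(self.forearm_velocity, dtype=float)
        self.upperarm_velocity = np.asarray(self.upperarm_velocity, dtype=float)
        n = self.time.size
        if n == 0:
            raise ValueError("empty trace")
        if self.forearm_velocity.size != n or self.upperarm_velocity.size != n:
            raise ValueError(
                "channel length mismatch: time has %d samples, forearm %d, upper arm %d"
                % (n, self.forearm_velocity.size, self.upperarm_velocity.size)
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (
            np.all(np.isfinite(self.forearm_velocity))
            and np.all(np.isfinite(self.upperarm_velocity))
        ):
            raise ValueError("velocity channels contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        """Trial duration in seconds (n_samples / rate)."""
        return self.n_samples / self.sampling_rate
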