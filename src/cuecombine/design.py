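"""Stimulus design: physical cue mappings, depth-level grids, and condition specs.

The experiment presents a target at depths around a reference plane (a computer
screen at 138 cm).  Depth is signalled by up to three cues: binocular disparity
(D), retinal size (S), and a newly learned auditory pitch cue (A).  All analysis
runs in *normalized depth units* — the reference is 0 and the extreme comparison
levels are ±1; the physical mappings below are provided for completeness and for
round-trip checks against the rig geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DisparityParams",
    "SizeParams",
    "AudioMapping",
    "DepthDesign",
    "ConditionSpec",
    "CONDITIONS",
    "disparity_offset",
    "angular_size",
    "pitch_for_depth",
]

#: default screen distance (cm)
SCREEN_DISTANCE_CM = 138.0
#: pitch at screen depth (Hz)
BASE_FREQ_HZ = 600.0
#: pitch change per cm of simulated depth (cents)
CENTS_PER_CM = 1.5
#: normalized comparison levels used by the method of constant stimuli
COMPARISON_LEVELS = tuple(
    s * v for v in (0.10, 0.25, 0.40, 0.55, 0.70, 0.85, 1.00) for s in (-1.0, 1.0)
)


@dataclass(frozen=True)
class DisparityParams:
    """Geometry of the disparity cue.

    Parameters
    ----------
    ioD : float
        Interocular distance in cm.
    D0 : float
        Screen (reference) distance in cm.
    noisy : bool
        Whether this is the uncertainty-added disparity variant (Du), in which
        per-dot offsets are jittered on the rig.  The simulator models Du as an
        inflation of the observer's disparity noise, not at the dot level.
    """

    ioD: float = 6.3
    D0: float = SCREEN_DISTANCE_CM
    noisy: bool = False

    def __post_init__(self) -> None:
        if self.ioD <= 0:
            raise ValueError("interocular distance must be positive")
        if self.D0 <= 0:
            raise ValueError("screen distance must be positive")


@dataclass(frozen=True)
class SizeParams:
    """Physical size of the square target / dots at screen level (cm)."""

    S0: float = 14.45  # ~6 deg at 138 cm

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class AudioMapping:
    """Depth-to-pitch mapping of the novel auditory cue.

    ``direction`` is the counterbalanced mapping sign: +1 maps further depth to
    higher pitch, -1 to lower pitch.
    """

    base_freq: float = BASE_FREQ_HZ
    cents_per_cm: float = CENTS_PER_CM
    direction: int = 1

    def __post_init__(self) -> None:
        if self.base_freq <= 0:
            raise ValueError("base frequency must be positive")
        if self.direction not in (1, -1):
            raise ValueError("mapping direction must be +1 or -1")


@dataclass(frozen=True)
class DepthDesign:
    """Comparison-level grid of the 2IFC task, in normalized depth units.

    The reference is at 0; the 14 comparison levels are ±{0.10 … 1.00} in steps
    of 0.15.  ``physical_step_cm`` converts one normalized unit to cm (10 cm in
    the study, so levels span ±1 cm to ±10 cm from the reference).  A small
    fraction of "easy" trials presents the two extreme depths against each other
    to keep observers engaged; they are flagged and excluded from fits by default.
    """

    reference: float = 0.0
    comparison_levels: tuple = COMPARISON_LEVELS
    physical_step_cm: float = 10.0
    side: str = "front"
    easy_trial_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.side not in ("front", "behind"):
            raise ValueError("side must be 'front' or 'behind'")
        if not 0.0 <= self.easy_trial_rate < 1.0:
            raise ValueError("easy_trial_rate must be in [0, 1)")

    @property
    def levels(self) -> np.ndarray:
        return np.asarray(self.comparison_levels, dtype=float)

    def n_easy(self, n_main: int) -> int:
        """Number of easy trials so they make up ``easy_trial_rate`` of the total."""
        r = self.easy_trial_rate
        return int(round(n_main * r / (1.0 - r)))


@dataclass(frozen=True)
class ConditionSpec:
    """One sensory condition of the experiment.

    Parameters
    ----------
    cues : tuple of str
        Subset of {"D", "S", "A"} presented.  "D" may be the noisy variant.
    disparity_noisy : bool
        Use the uncertainty-added disparity cue (Du).
    conflict_delta : float
        Signed offset (normalized units) applied to the non-disparity cue of the
        *reference* stimulus; nonzero only in bimodal conflict conditions.
    incongruent : bool
        The comparison's second cue moves opposite to the learned mapping.
    """

    cues: tuple = ("D",)
    disparity_noisy: bool = False
    conflict_delta: float = 0.0
    incongruent: bool = False

    def __post_init__(self) -> None:
        cues = tuple(self.cues)
        object.__setattr__(self, "cues", cues)
        if not cues or not set(cues) <= {"D", "S", "A"}:
            raise ValueError(f"invalid cue set {cues!r}")
        if len(cues) != len(set(cues)):
            raise ValueError("duplicate cues")
        if self.conflict_delta != 0.0 and len(cues) < 2:
            raise ValueError("cue conflict requires a bimodal condition")
        if self.incongruent and len(cues) < 2:
            raise ValueError("incongruence requires a bimodal condition")
        if self.incongruent and self.conflict_delta != 0.0:
            raise ValueError("conflict and incongruence are mutually exclusive")
        if self.disparity_noisy and "D" not in cues:
            raise ValueError("disparity_noisy requires the disparity cue")

    @property
    def is_bimodal(self) -> bool:
        return len(self.cues) == 2

    @property
    def other_cue(self) -> str | None:
        """The non-disparity cue of a bimodal pairing."""
        others = [c for c in self.cues if c != "D"]
        return others[0] if len(self.cues) == 2 and len(others) == 1 else None

    @property
    def label(self) -> str:
        base = "".join(("Du" if c == "D" and self.disparity_noisy else c) for c in self.cues)
        if self.conflict_delta > 0:
            return base + "+"
        if self.conflict_delta < 0:
            return base + "-"
        if self.incongruent:
            return base + "i"
        return base


def _cond(cues, noisy=False, conflict=0.0, incongruent=False) -> ConditionSpec:
    return ConditionSpec(tuple(cues), disparity_noisy=noisy, conflict_delta=conflict,
                         incongruent=incongruent)


#: canonical condition registry keyed by label; conflict conditions are built
#: per participant (δ depends on the participant's JND) via
#: :func:`condition_from_label`.
CONDITIONS = {
    "D": _cond("D"),
    "Du": _cond("D", noisy=True),
    "S": _cond("S"),
    "A": _cond("A"),
    "DS": _cond("DS"),
    "DA": _cond("DA"),
    "DuS": _cond("DS", noisy=True),
    "DuA": _cond("DA", noisy=True),
    "DSi": _cond("DS", incongruent=True),
    "DAi": _cond("DA", incongruent=True),
}


def condition_from_label(label: str, conflict_delta: float = 0.0) -> ConditionSpec:
    """Build a :class:`ConditionSpec` from a condition label such as ``"DuS+"``.

    For conflict labels (trailing ``+`` or ``-``) ``conflict_delta`` gives the
    magnitude |δ|; the sign is taken from the label.
    """
    sign = 0
    base = label
    if label.endswith("+"):
        sign, base = 1, label[:-1]
    elif label.endswith("-"):
        sign, base = -1, label[:-1]
    if sign != 0:
        if conflict_delta <= 0:
            raise ValueError("conflict conditions need a positive conflict_delta magnitude")
        spec = CONDITIONS[base]
        return ConditionSpec(spec.cues, disparity_noisy=spec.disparity_noisy,
                             conflict_delta=sign * conflict_delta)
    try:
        return CONDITIONS[base]
    except KeyError:
        raise KeyError(f"unknown condition label {label!r}") from None


# ---------------------------------------------------------------------------
# physical cue mappings


def disparity_offset(D: float, params: DisparityParams = DisparityParams()) -> float:
    """Horizontal half-image offset (cm) rendering a target at distance ``D`` cm.

    offset = ioD * (D - D0) / (2 D): zero at the screen plane, positive beyond it.
    """
    D = float(D)
    if D <= 0:
        raise ValueError("target distance must be positive")
    return params.ioD * (D - params.D0) / (2.0 * D)


def angular_size(D: float, params: SizeParams = SizeParams()) -> float:
    """Angular size (radians) of a target of physical size S0 at distance ``D`` cm.

    stimSize = 2 atan(S0 / (2 D)); strictly decreasing in D.
    """
    D = float(D)
    if D <= 0:
        raise ValueError("target distance must be positive")
    return 2.0 * math.atan(params.S0 / (2.0 * D))


def pitch_for_depth(delta_cm: float, mapping: AudioMapping = AudioMapping()) -> float:
    """Pitch (Hz) for a signed depth ``delta_cm`` from the screen plane.

    f = base_freq * 2 ** (direction * cents_per_cm * delta_cm / 1200).
    """
    cents = mapping.direction * mapping.cents_per_cm * float(delta_cm)
    return mapping.base_freq * 2.0 ** (cents / 1200.0)
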