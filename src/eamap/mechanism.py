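"""Tachycardia-mechanism classification from cycle-length coverage and
induction-protocol response.

Microreentry is called when activation mapping covers more than 70% of
the tachycardia cycle length.  With coverage below 50%, the focal
mechanisms are split by the stimulation protocol: triggered activity is
inducible and terminated by programmed stimulation; enhanced automaticity
is not pacing-inducible and requires isoproterenol.  Coverage between 50%
and 70% is deliberately left indeterminate rather than silently guessed.
All inequalities are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

MICROREENTRY_COVERAGE = 0.70
FOCAL_COVERAGE = 0.50

LABELS = ("microreentry", "triggered", "automaticity", "indeterminate")


@dataclass
class MechanismCall:
    label: str
    coverage_fraction: float
    flags: dict = field(default_factory=dict)
    note: str = ""


def coverage_fraction(mapped_span: float, tcl: float) -> float:
    """Fraction of the tachycardia cycle length covered by the map."""
    if tcl <= 0:
        raise ValueError("tcl must be positive")
    if mapped_span < 0:
        raise ValueError("mapped_span must be >= 0")
    return float(mapped_span) / float(tcl)


def classify_mechanism(
    coverage: float,
    inducible_by_pes: bool,
    terminated_by_pes: bool,
    requires_isoproterenol: bool,
) -> MechanismCall:
    """Label the arrhythmia mechanism.

    microreentry if coverage > 0.70; else triggered if coverage < 0.50 and
    inducible + terminated by programmed stimulation; else automaticity if
    coverage < 0.50, not pacing-inducible and isoproterenol-dependent;
    anything else (including contradictory flags) is indeterminate.
    """
    flags = dict(
        inducible_by_pes=bool(inducible_by_pes),
        terminated_by_pes=bool(terminated_by_pes),
        requires_isoproterenol=bool(requires_isoproterenol),
    )
    note = ""
    if coverage > MICROREENTRY_COVERAGE:
        label = "microreentry"
    elif coverage < FOCAL_COVERAGE:
        if inducible_by_pes and requires_isoproterenol:
            label = "indeterminate"
            note = "contradictory induction flags (pacing-inducible yet isoproterenol-dependent)"
            warnings.warn(note, stacklevel=2)
        elif inducible_by_pes and terminated_by_pes:
            label = "triggered"
        elif (not inducible_by_pes) and requires_isoproterenol:
            label = "automaticity"
        else:
            label = "indeterminate"
            note = "induction flags match no focal-mechanism criterion"
    else:
        label = "indeterminate"
        note = "coverage in [0.50, 0.70] is outside every mechanism criterion"
    return MechanismCall(label=label, coverage_fraction=float(coverage), flags=flags, note=note)
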