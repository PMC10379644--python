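"""Canonical label sets shared across the package.

The experimental design is a two-group (cochlear-implant users vs.
normally-hearing controls), three-condition (SNR difficulty), two-trial-type
(sentence vs. null) speeded yes/no task.  Everything downstream — the
generator, the accumulator model, the metrics — indexes cells by these
ordered tuples, so they live in one place.
"""

from __future__ import annotations

#: Ordered difficulty conditions (most to least favourable SNR).
CONDITIONS: tuple[str, ...] = ("Easy", "Med", "Hard")

#: Trial types: sentence trials require listening, null trials are an
#: instructed button press with the sentence muted.
TRIAL_TYPES: tuple[str, ...] = ("sentence", "null")

#: Accumulator labels for the two-choice race.
ACCUMULATORS: tuple[str, ...] = ("correct", "incorrect")

#: Default group labels (patient group first).
GROUPS: tuple[str, ...] = ("CI", "NH")

#: Visual-analog rating questions: effort, intelligibility, disengagement.
QUESTIONS: tuple[str, ...] = ("EF", "IN", "TD")


def condition_index(condition: str) -> int:
    try:
        return CONDITIONS.index(condition)
    except ValueError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        ) from None


def trial_type_index(trial_type: str) -> int:
    try:
        return TRIAL_TYPES.index(trial_type)
    except ValueError:
        raise ValueError(
            f"unknown trial type {trial_type!r}; expected one of {TRIAL_TYPES}"
        ) from None


def accumulator_index(choice: str) -> int:
    try:
        return ACCUMULATORS.index(choice)
    except ValueError:
        raise ValueError(
            f"unknown choice {choice!r}; expected one of {ACCUMULATORS}"
        ) from None
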