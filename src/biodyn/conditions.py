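"""Treatment conditions of the ex vivo assay.

Bone-marrow wells are treated with doxorubicin at four concentrations
(0.1, 1, 10, 100 uM) alongside a 0.1% DMSO vehicle control, four tissue
replicates per condition.
"""

from __future__ import annotations

from .errors import ConfigurationError

#: Vehicle-control label.
CTRL = "CTRL"

#: Condition labels in increasing dose order (control first).
CONDITIONS: tuple[str, ...] = (CTRL, "0.1", "1", "10", "100")

#: Doxorubicin concentration in uM per condition (control carries no drug).
DOSES_UM: dict[str, float] = {CTRL: 0.0, "0.1": 0.1, "1": 1.0, "10": 10.0, "100": 100.0}

#: Replicate wells per condition.
N_REPLICATES = 4


def validate_condition(label: str) -> str:
    """Return ``label`` if it is a recognized condition, else raise.

    Raises
    ------
    ConfigurationError
        Listing the valid condition labels.
    """
    if label not in CONDITIONS:
        raise ConfigurationError(
            f"unknown condition {label!r}; valid conditions are {list(CONDITIONS)}"
        )
    return label


def condition_display(label: str) -> str:
    """Human-readable condition name used in biomarker names.

    >>> condition_display("1")
    'Dox 1'
    >>> condition_display("CTRL")
    'CTRL'
    """
    validate_condition(label)
    return label if label == CTRL else f"Dox {label}"


def dose_pairs() -> list[tuple[str, str]]:
    """All ordered (numerator, reference) condition pairs with the
    numerator at a higher dose than the reference (control = dose 0)."""
    pairs = []
    for i, ref in enumerate(CONDITIONS):
        for num in CONDITIONS[i + 1 :]:
            pairs.append((num, ref))
    return pairs
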