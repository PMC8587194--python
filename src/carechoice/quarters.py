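"""Calendar-quarter arithmetic.

All dates in the package are integer quarter indices relative to the start of
the study window (index 0 = first quarter, e.g. 2008Q1 for a 2008-2017 study).
Finer real-world dates are floored to the quarter that contains them before
they enter any computation.
"""

from __future__ import annotations

DEFAULT_START_YEAR = 2008


def quarter_label(q: int, start_year: int = DEFAULT_START_YEAR) -> str:
    """Human-readable label ('2008Q1') for quarter index ``q``."""
    if q < 0:
        raise ValueError(f"quarter index must be non-negative, got {q}")
    return f"{start_year + q // 4}Q{q % 4 + 1}"


def parse_quarter(label: str, start_year: int = DEFAULT_START_YEAR) -> int:
    """Inverse of :func:`quarter_label`."""
    year_s, _, qpart = label.partition("Q")
    year, qq = int(year_s), int(qpart)
    if not 1 <= qq <= 4:
        raise ValueError(f"malformed quarter label {label!r}")
    return (year - start_year) * 4 + (qq - 1)


def year_trend(q, origin_quarter: int = 0):
    """Integer years elapsed since ``origin_quarter`` (floor of quarters/4).

    This is the linear year-trend regressor used for attribute-by-time
    interaction terms: admissions in the first study year carry 0, the second
    year 1, and so on.
    """
    return (q - origin_quarter) // 4
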