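"""Small shared helpers."""

from __future__ import annotations


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage of ``part`` in ``whole`` rounded to ``ndigits`` decimals.

    Used for cohort bookkeeping (exclusion rates, demographic proportions).
    """
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round(100.0 * part / whole, ndigits)
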