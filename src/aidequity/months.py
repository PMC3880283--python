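"""Century-month-code (CMC) helpers.

Calendar months are encoded DHS-style as integer months since January 1900:
``cmc = (year - 1900) * 12 + month`` with ``month`` in 1..12, so January 1900
is 1 and December 2012 is 1356.
"""


def cmc(year: int, month: int) -> int:
    """Return the century month code of a calendar (year, month)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return (year - 1900) * 12 + month


def cmc_year(code) -> int:
    """Calendar year containing CMC month ``code`` (vectorized over arrays)."""
    return 1900 + (code - 1) // 12


def year_start_cmc(year: int) -> int:
    """CMC of January of ``year``."""
    return cmc(year, 1)
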