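"""Shared text and rounding conventions.

All text entering the pipeline is normalized to NFC so that mixed
Chinese/Latin surfaces compare bit-stably; all character offsets in the
package are 0-based, half-open, and refer to the NFC form. Percentages are
rounded half-up (commercial rounding) at one decimal, the convention used
throughout the reported tables.
"""

from __future__ import annotations

import unicodedata
from decimal import ROUND_HALF_UP, Decimal


def nfc(text: str) -> str:
    """Return the NFC normalization of *text*."""
    return unicodedata.normalize("NFC", text)


def round_half_up(value: float, digits: int = 1) -> float:
    """Round *value* half-up at *digits* decimals (5 always rounds away from 0)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, digits: int = 1) -> float | None:
    """100 * numerator / denominator, rounded half-up; None for an empty denominator.

    Division is done in decimal arithmetic so the half-up rule applies to the
    true quotient, not to a binary-float approximation of it.
    """
    if denominator == 0:
        return None
    quantum = Decimal(1).scaleb(-digits)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def is_break_char(ch: str) -> bool:
    """True for whitespace and punctuation: segmentation never joins across these."""
    if ch.isspace():
        return True
    return unicodedata.category(ch).startswith("P")
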