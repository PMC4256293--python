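"""Colour-opponency indices, relative excitations and Troje categories.

Chromatic information in the fly visual system arises from signed
comparisons of excitations across receptor classes. The index that best
predicts tsetse attraction to visual baits is the unweighted combination

    + E_R7y − E_R8y − E_R7p

(the UV-blue receptor R7y contributes positively; the green-yellow R8y and
the low-UV R7p negatively). With all excitations at the background level of
0.5 this default index evaluates to −0.5 — a handy reference point:
"background = −0.5". A two-term variant + E_R7y − E_R8y and arbitrary
user-supplied weightings (e.g. study-fitted regression coefficients) are
expressed through the same :class:`OpponencyCoefficients` machinery.

Troje-style categorisation instead reduces a spectrum to the signs of the
two within-ommatidium opponent differences, R7y−R8y ('y') and R7p−R8p
('p'), yielding four colour categories y±p±.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .receptors import RECEPTOR_CLASSES, ExcitationVector


class OpponencyError(ValueError):
    pass


@dataclass(frozen=True)
class OpponencyCoefficients:
    """A signed weighting of receptor excitations defining an opponency index."""

    weights: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        unknown = [c for c in self.weights if c not in RECEPTOR_CLASSES]
        if unknown:
            raise OpponencyError(f"unknown receptor classes in weights: {unknown}")
        if not any(w != 0 for w in self.weights.values()):
            raise OpponencyError("at least one weight must be non-zero")

    def weight(self, label: str) -> float:
        return float(self.weights.get(label, 0.0))


#: The attraction-predicting index + E_R7y − E_R8y − E_R7p.
DEFAULT_INDEX = OpponencyCoefficients(
    weights={"R7y": 1.0, "R8y": -1.0, "R7p": -1.0}, name="R7y-R8y-R7p")

#: The two-receptor opponent pair + E_R7y − E_R8y.
YY_INDEX = OpponencyCoefficients(weights={"R7y": 1.0, "R8y": -1.0}, name="R7y-R8y")


def parse_index(expression: str) -> OpponencyCoefficients:
    """Parse an index expression like ``"R7y-R8y-R7p"`` or ``"+R7y-R8y"``.

    Terms are receptor labels joined by ``+``/``-`` signs; unit weights only.
    """
    expr = expression.replace(" ", "")
    if not expr:
        raise OpponencyError("empty index expression")
    weights: dict[str, float] = {}
    sign = 1.0
    token = ""
    # 'R1-6' contains a hyphen, so match labels greedily, longest first.
    labels = sorted(RECEPTOR_CLASSES, key=len, reverse=True)
    i = 0
    while i < len(expr):
        ch = expr[i]
        matched = None
        for lab in labels:
            if expr.startswith(lab, i):
                matched = lab
                break
        if matched:
            weights[matched] = weights.get(matched, 0.0) + sign
            sign = 1.0
            i += len(matched)
        elif ch == "+":
            i += 1
        elif ch == "-":
            sign = -sign
            i += 1
        else:
            raise OpponencyError(f"cannot parse index expression at '{expr[i:]}'")
    return OpponencyCoefficients(weights=weights, name=expression)


def opponency_index(
    E: ExcitationVector | Mapping[str, float],
    coeffs: OpponencyCoefficients = DEFAULT_INDEX,
) -> float:
    """Σ_c weight_c × E_c. Linear in the excitations.

    For the default coefficients the value lies in (−2, 1): each E is in
    [0, 1) and the weights are (+1, −1, −1).
    """
    e = E.E if isinstance(E, ExcitationVector) else E
    return float(sum(coeffs.weight(c) * e[c] for c in RECEPTOR_CLASSES if c in e))


def relative_excitations(E: ExcitationVector | Mapping[str, float]) -> dict[str, float]:
    """Each excitation as a proportion of the mean over the five classes.

    The returned values average exactly 1. An all-zero vector has no defined
    proportions and raises.
    """
    e = E.E if isinstance(E, ExcitationVector) else E
    arr = np.array([e[c] for c in RECEPTOR_CLASSES], dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise OpponencyError("relative excitations undefined for an all-zero vector")
    rel = arr / mean
    return dict(zip(RECEPTOR_CLASSES, rel.tolist()))


@dataclass(frozen=True)
class ColourCategory:
    """One of the four Troje colour categories, from the signs of y and p."""

    y_sign: str
    p_sign: str

    def __post_init__(self) -> None:
        if self.y_sign not in "+-" or self.p_sign not in "+-":
            raise OpponencyError("signs must be '+' or '-'")

    @property
    def label(self) -> str:
        return f"y{self.y_sign}p{self.p_sign}"


def troje_category(
    E: ExcitationVector | Mapping[str, float],
    *,
    return_boundary: bool = False,
):
    """Categorise by sign of the R7y−R8y ('y') and R7p−R8p ('p') differences.

    A zero difference maps to '+' so the categorisation is total; with
    ``return_boundary=True`` a second value flags whether either difference
    was exactly zero (a boundary case).
    """
    e = E.E if isinstance(E, ExcitationVector) else E
    dy = e["R7y"] - e["R8y"]
    dp = e["R7p"] - e["R8p"]
    cat = ColourCategory(y_sign="+" if dy >= 0 else "-",
                         p_sign="+" if dp >= 0 else "-")
    if return_boundary:
        return cat, (dy == 0 or dp == 0)
    return cat


def index_table(
    excitations: pd.DataFrame,
    coeffs: OpponencyCoefficients = DEFAULT_INDEX,
) -> pd.Series:
    """Opponency index for every row of an excitation table (E_* columns)."""
    vals = np.zeros(len(excitations))
    for c in RECEPTOR_CLASSES:
        w = coeffs.weight(c)
        if w:
            vals = vals + w * excitations[f"E_{c}"].to_numpy(dtype=float)
    return pd.Series(vals, index=excitations.index, name=coeffs.name)


def categorise_table(excitations: pd.DataFrame) -> pd.DataFrame:
    """Troje category per row of an excitation table.

    Returns columns ``y_sign``, ``p_sign``, ``label`` and ``boundary``.
    """
    rows = []
    for _, row in excitations.iterrows():
        e = {c: float(row[f"E_{c}"]) for c in RECEPTOR_CLASSES}
        cat, boundary = troje_category(e, return_boundary=True)
        rows.append({"y_sign": cat.y_sign, "p_sign": cat.p_sign,
                     "label": cat.label, "boundary": boundary})
    return pd.DataFrame(rows, index=excitations.index)
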