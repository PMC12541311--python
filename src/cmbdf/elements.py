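"""Periodic-table metadata and element-specific scaling factors.

Every many-body distribution is weighted by a scalar encoding the chemical
identity of the participating elements.  The per-element factor is

    A(Z) = ln(P + 1) * G

where ``P`` and ``G`` are the period and IUPAC group (1-18) of element ``Z``,
and the weight of a nu-body term is the geometric mean of the per-element
factors of the nu-1 non-central atoms,

    A_nu(Z_1, ..., Z_{nu-1}) = (prod_j A(Z_j)) ** (1 / (nu - 1)).

The functional form of ``A`` is configurable (``scaling_function``) since
only its qualitative role -- separating chemical species smoothly -- matters
to the representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

__all__ = [
    "ElementInfo",
    "UnknownElementError",
    "element_info",
    "period_group",
    "scaling_factor",
    "many_body_scaling",
    "symbol_to_z",
    "z_to_symbol",
]

#: Default width (angstrom) of the Gaussian basis function placed on each
#: atom.  Uniform across elements so a single four-body effective width
#: sigma/sqrt(6) suffices; per-element widths are accepted by the feature
#: configuration.
DEFAULT_SIGMA = 0.6


class UnknownElementError(KeyError):
    """Raised for an atomic number or symbol absent from the bundled table."""


@dataclass(frozen=True)
class ElementInfo:
    """Periodic-table record for one element."""

    Z: int
    symbol: str
    period: int
    group: int
    sigma: float = DEFAULT_SIGMA


def _load_table() -> dict[int, ElementInfo]:
    table: dict[int, ElementInfo] = {}
    text = (
        resources.files("cmbdf").joinpath("data/periodic_table.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, z, period, group = line.split("\t")
        info = ElementInfo(int(z), symbol, int(period), int(group))
        table[info.Z] = info
    return table


_TABLE: dict[int, ElementInfo] = _load_table()
_BY_SYMBOL: dict[str, ElementInfo] = {e.symbol: e for e in _TABLE.values()}


def element_info(Z: int) -> ElementInfo:
    """Return the :class:`ElementInfo` record for atomic number ``Z``."""
    try:
        return _TABLE[int(Z)]
    except (KeyError, ValueError) as exc:
        raise UnknownElementError(f"unknown element: Z={Z!r}") from exc


def symbol_to_z(symbol: str) -> int:
    """Atomic number of an element symbol (case sensitive, e.g. ``"Cl"``)."""
    try:
        return _BY_SYMBOL[symbol].Z
    except KeyError as exc:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from exc


def z_to_symbol(Z: int) -> str:
    return element_info(Z).symbol


def period_group(Z: int) -> tuple[int, int]:
    """IUPAC period and group (1-18 convention) of element ``Z``."""
    info = element_info(Z)
    return info.period, info.group


def scaling_factor(
    Z: int, form: Callable[[int, int], float] | None = None
) -> float:
    """Element-identity scaling A(Z).

    Parameters
    ----------
    Z
        Atomic number.
    form
        Optional override ``form(period, group) -> float``; the default is
        ``ln(period + 1) * group``.
    """
    period, group = period_group(Z)
    if form is not None:
        return float(form(period, group))
    return math.log(period + 1) * group


def many_body_scaling(
    Zs: Sequence[int] | Iterable[int],
    nu: int,
    form: Callable[[int, int], float] | None = None,
) -> float:
    """Geometric mean of A(Z) over the ``nu - 1`` non-central atoms."""
    Zs = list(Zs)
    if len(Zs) != nu - 1:
        raise ValueError(
            f"a {nu}-body weight needs {nu - 1} atomic numbers, got {len(Zs)}"
        )
    log_sum = sum(math.log(scaling_factor(Z, form)) for Z in Zs)
    return math.exp(log_sum / (nu - 1))
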