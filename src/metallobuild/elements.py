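"""Element data tables and default electronic-state assignment.

The table shipped in ``data/elements.csv`` holds, per element: atomic
number, a single-bond covalent radius (Å), a van der Waals radius (Å) and —
for metals — an ordered list of common oxidation states (most common
first) and an ordered list of common coordination numbers. Radii follow
the standard literature compilations (Cordero-type covalent radii,
Alvarez/Bondi-type vdW radii); the per-metal oxidation/CN defaults are a
reconstruction from standard coordination-chemistry references and are
documented as such in the methods note.

Spin defaults are not tabulated: they are derived at load time by Hund
(high-spin) filling of the relevant d or f subshell of the metal ion, which
gives an unambiguous multiplicity whose parity is consistent with the
electron count by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .errors import InconsistentStateError, UnsupportedElementError

__all__ = [
    "ElementRecord",
    "ElectronicState",
    "get_element",
    "covalent_radius",
    "vdw_radius",
    "hund_multiplicity",
    "assign_defaults",
    "actinide_proxy",
    "ELEMENTS",
]


@dataclass(frozen=True)
class ElementRecord:
    symbol: str
    atomic_number: int
    covalent_radius: float  # Å
    vdw_radius: float  # Å
    default_oxidation_states: tuple[int, ...]
    default_spins: dict[int, int]  # oxidation -> spin multiplicity
    default_CNs: tuple[int, ...]


@dataclass(frozen=True)
class ElectronicState:
    """Complete electronic specification of a complex."""

    metal_oxidation: int
    total_charge: int
    spin_multiplicity: int

    def __post_init__(self):
        if self.spin_multiplicity < 1:
            raise InconsistentStateError(
                f"spin multiplicity must be >= 1, got {self.spin_multiplicity}"
            )


# ---------------------------------------------------------------------------
# subshell bookkeeping

_LN_RANGE = range(57, 72)  # La..Lu
_AC_RANGE = range(89, 104)  # Ac..Lr
_D_BLOCKS = {  # z-range -> electrons in noble-gas core preceding the nd shell
    range(21, 31): 18,  # 3d: Sc..Zn
    range(39, 49): 36,  # 4d: Y..Cd
    range(72, 81): 68,  # 5d: Hf..Hg (68 = Xe core + 4f14)
}


def _unpaired_electrons(z: int, oxidation: int) -> int:
    """High-spin (Hund) unpaired-electron count for a metal ion.

    f-block ions fill the (n-2)f shell, d-block the (n-1)d shell;
    main-group ions are closed-shell when their electron count is even.
    Out-of-range subshell counts (e.g. negative formal d counts from an
    unusual oxidation override) fall back to the parity rule.
    """
    if z in _LN_RANGE or z in _AC_RANGE:
        base = 54 if z in _LN_RANGE else 86
        n_f = z - base - oxidation
        if 0 <= n_f <= 14:
            return n_f if n_f <= 7 else 14 - n_f
        return (z - oxidation) % 2
    for block, core in _D_BLOCKS.items():
        if z in block:
            n_d = z - core - oxidation
            if 0 <= n_d <= 10:
                return n_d if n_d <= 5 else 10 - n_d
            break
    return (z - oxidation) % 2


def hund_multiplicity(symbol: str, oxidation: int) -> int:
    """Spin multiplicity (2S+1) from high-spin filling of the metal ion."""
    rec = get_element(symbol)
    return _unpaired_electrons(rec.atomic_number, oxidation) + 1


# ---------------------------------------------------------------------------
# table loading

def _parse_int_list(text: str) -> tuple[int, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(int(tok) for tok in text.split(";"))


def _load_table() -> dict[str, ElementRecord]:
    table: dict[str, ElementRecord] = {}
    path = resources.files("metallobuild.data") / "elements.csv"
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            z = int(row["z"])
            ox_states = _parse_int_list(row["ox_states"])
            spins = {
                ox: _unpaired_electrons(z, ox) + 1 for ox in ox_states
            }
            rec = ElementRecord(
                symbol=row["symbol"],
                atomic_number=z,
                covalent_radius=float(row["rcov"]),
                vdw_radius=float(row["rvdw"]),
                default_oxidation_states=ox_states,
                default_spins=spins,
                default_CNs=_parse_int_list(row["cns"]),
            )
            table[rec.symbol] = rec
    return table


ELEMENTS: dict[str, ElementRecord] = _load_table()
_BY_Z = {rec.atomic_number: rec for rec in ELEMENTS.values()}


def get_element(symbol: str) -> ElementRecord:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise UnsupportedElementError(f"unknown element symbol {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    return get_element(symbol).covalent_radius


def vdw_radius(symbol: str) -> float:
    return get_element(symbol).vdw_radius


# ---------------------------------------------------------------------------
# defaults

def actinide_proxy(symbol: str) -> str:
    """Same-group lanthanide stand-in for an actinide metal center.

    Backends parametrized only up to Z = 88 cannot treat actinides; the
    conventional workaround is to substitute the lanthanide one row up
    (Ac→La, Th→Ce, ..., Lr→Lu), which carries the same f-electron count at
    a given oxidation state. Non-actinides pass through unchanged, which
    makes the function idempotent.
    """
    rec = get_element(symbol)
    if rec.atomic_number in _AC_RANGE:
        return _BY_Z[rec.atomic_number - 32].symbol
    return symbol


def assign_defaults(
    metal: str,
    ligand_charges: Sequence[int] = (),
    overrides: Optional[dict] = None,
) -> ElectronicState:
    """Fill in oxidation state, total charge and spin multiplicity.

    Parameters
    ----------
    metal : element symbol of the metal center.
    ligand_charges : formal charge of each ligand (closed-shell assumed).
    overrides : optional dict with any of ``metal_oxidation``,
        ``total_charge``, ``spin_multiplicity``; honored verbatim and
        validated for internal consistency.

    The default oxidation state is the first (most common) entry of the
    element table; the default multiplicity is the high-spin Hund value for
    the resulting ion. Because every closed-shell ligand carries an even
    electron count, total-electron parity is fixed by Z(metal) − oxidation
    alone, which is what the multiplicity check uses.
    """
    rec = get_element(metal)
    overrides = dict(overrides or {})
    lig_sum = int(sum(ligand_charges))

    oxidation = overrides.pop("metal_oxidation", None)
    total = overrides.pop("total_charge", None)
    multiplicity = overrides.pop("spin_multiplicity", None)
    if overrides:
        raise InconsistentStateError(
            f"unknown override field(s): {sorted(overrides)}"
        )

    if oxidation is None:
        if total is not None:
            oxidation = total - lig_sum
        elif rec.default_oxidation_states:
            oxidation = rec.default_oxidation_states[0]
        else:
            raise UnsupportedElementError(
                f"{metal} has no default oxidation state; provide an override"
            )
    if total is None:
        total = oxidation + lig_sum
    elif total != oxidation + lig_sum:
        raise InconsistentStateError(
            f"total charge {total} inconsistent with oxidation {oxidation} "
            f"+ ligand charges {lig_sum}"
        )

    valence_parity = (rec.atomic_number - oxidation) % 2
    if multiplicity is None:
        multiplicity = _unpaired_electrons(rec.atomic_number, oxidation) + 1
    elif multiplicity < 1 or (multiplicity - 1) % 2 != valence_parity:
        raise InconsistentStateError(
            f"multiplicity {multiplicity} has impossible parity for "
            f"{metal}({oxidation:+d}) with closed-shell ligands"
        )

    return ElectronicState(
        metal_oxidation=int(oxidation),
        total_charge=int(total),
        spin_multiplicity=int(multiplicity),
    )
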