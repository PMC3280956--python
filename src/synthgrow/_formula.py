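"""Tiny molecular-formula mass helper for reaction mass bookkeeping."""

from __future__ import annotations

import re

from rdkit import Chem

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str | None) -> float:
    """Average mass (Da) of a dot-separated formula string, e.g. "HCl.HCl".

    An empty or None formula has mass 0 (no leaving group / no reagent).
    """
    if not formula:
        return 0.0
    pt = Chem.GetPeriodicTable()
    total = 0.0
    for part in formula.split("."):
        pos = 0
        for m in _TOKEN.finditer(part):
            if m.start() != pos:
                raise ValueError(f"bad formula {formula!r}")
            pos = m.end()
            sym, count = m.group(1), int(m.group(2) or 1)
            w = pt.GetAtomicWeight(sym)
            if w == 0.0 and sym != "H":
                raise ValueError(f"unknown element {sym!r} in {formula!r}")
            total += w * count
        if pos != len(part):
            raise ValueError(f"bad formula {formula!r}")
    return total
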