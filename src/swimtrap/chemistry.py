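"""Ion bookkeeping for the paired-droplet fusion assay.

When a cell-bearing droplet is fused with a perturbant droplet, the combined
droplet's ion concentrations are the volume-weighted means of the two parent
solutions.  This module predicts the post-fusion concentrations (default:
equal volumes, ratio 0.5) and renders a pre/post comparison table, rounding
to 3 significant figures with half-up rounding and reporting trace species
(< 0.075 mM) as "negligible".  No activity coefficients or speciation — pure
conservation of solute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["IonSolution", "mix", "fusion_report", "round_sig",
           "KNOWN_IONS", "PO_MEDIUM", "KCL_10MM"]

#: controlled vocabulary of ion names; extend in place for exotic media
KNOWN_IONS = {"Na+", "K+", "Ca2+", "Mg2+", "Cl-", "SO4 2-", "NO3-",
              "HPO4 2-"}

#: concentrations below this (mM) are reported as "negligible"
NEGLIGIBLE_MM = 0.075


@dataclass
class IonSolution:
    """A named map of ion concentrations in mM with a volume weight."""

    concentrations: dict = field(default_factory=dict)
    volume_fraction: float = 1.0

    def __post_init__(self):
        for ion, c in self.concentrations.items():
            if ion not in KNOWN_IONS:
                raise ValueError(
                    f"unknown ion {ion!r}; add it to KNOWN_IONS first")
            if c < 0:
                raise ValueError(f"negative concentration for {ion}: {c}")

    def __getitem__(self, ion: str) -> float:
        return self.concentrations.get(ion, 0.0)

    def ions(self):
        return set(self.concentrations)


#: marine-medium cell-droplet composition before fusion (mM)
PO_MEDIUM = IonSolution({
    "Na+": 395.0, "K+": 8.33, "Ca2+": 8.75, "Mg2+": 44.5,
    "Cl-": 459.0, "SO4 2-": 23.6, "NO3-": 1.1, "HPO4 2-": 0.1,
})

#: the perturbant droplet: 10 mM KCl in water
KCL_10MM = IonSolution({"K+": 10.0, "Cl-": 10.0})


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures with half-up ties (9.165 -> 9.17,
    22.25 -> 22.3), as used when comparing against reported tables."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(value)).quantize(quantum,
                                               rounding=ROUND_HALF_UP))


def mix(a: IonSolution, b: IonSolution, ratio: float = 0.5) -> IonSolution:
    """Volume-weighted mixture: c_out = ratio·c_a + (1-ratio)·c_b.

    ``ratio`` is the volume fraction of solution ``a`` in (0, 1).  Ions
    present in only one parent count as 0 mM in the other, so total solute
    amount is conserved exactly.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    ions = a.ions() | b.ions()
    out = {ion: ratio * a[ion] + (1 - ratio) * b[ion] for ion in ions}
    return IonSolution(out, volume_fraction=1.0)


def fusion_report(pre: IonSolution, perturbant: IonSolution,
                  ratio: float = 0.5) -> pd.DataFrame:
    """Pre/post-fusion comparison table over the union of ions.

    Columns: ``pre_mM`` and ``post_mM`` (exact), plus ``post_reported`` — the
    3-significant-figure half-up value as a string, with concentrations below
    0.075 mM rendered "negligible".  Row order follows the pre-fusion
    solution, then any perturbant-only ions.
    """
    post = mix(pre, perturbant, ratio)
    order = list(pre.concentrations) + sorted(post.ions() - pre.ions())
    rows = []
    for ion in order:
        c_post = post[ion]
        reported = ("negligible" if c_post < NEGLIGIBLE_MM
                    else f"{round_sig(c_post):g}")
        rows.append({"ion": ion, "pre_mM": pre[ion], "post_mM": c_post,
                     "post_reported": reported})
    return pd.DataFrame(rows).set_index("ion")
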