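"""Cohort-level report helpers: phenotype cross-tabulation and friends."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import validate_phenotypes


@dataclass
class Crosstab:
    """2x2 combination counts for two insecticides.

    Cells are keyed RR / RS / SR / SS where the first letter is the
    first insecticide's phenotype (R = resistant) and the second letter
    the second insecticide's.
    """

    insecticide_a: str
    insecticide_b: str
    rr: int
    rs: int
    sr: int
    ss: int
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.rr + self.rs + self.sr + self.ss

    @property
    def marginals(self) -> dict[str, int]:
        return {f"{self.insecticide_a}_resistant": self.rr + self.rs,
                f"{self.insecticide_b}_resistant": self.rr + self.sr}


def phenotype_crosstab(phenotypes: pd.DataFrame, insecticide_a: str,
                       insecticide_b: str) -> Crosstab:
    """Count RR/RS/SR/SS phenotype combinations across two insecticides.

    Individuals missing either label are excluded and counted.
    """
    validate_phenotypes(phenotypes)
    a = phenotypes[insecticide_a]
    b = phenotypes[insecticide_b]
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    res_a, res_b = a == "resistant", b == "resistant"
    return Crosstab(
        insecticide_a=insecticide_a, insecticide_b=insecticide_b,
        rr=int((res_a & res_b).sum()), rs=int((res_a & ~res_b).sum()),
        sr=int((~res_a & res_b).sum()), ss=int((~res_a & ~res_b).sum()),
        n_excluded=int((~ok).sum()),
    )


def crosstab_from_marginals(total: int, resistant_a: int, resistant_b: int,
                            both_resistant: int,
                            insecticide_a: str = "malathion",
                            insecticide_b: str = "permethrin") -> Crosstab:
    """Recover the 2x2 combination counts from printed marginals by
    inclusion-exclusion.

    RS = resistant_a - both, SR = resistant_b - both,
    SS = total - RR - RS - SR.  Inconsistent marginals (any negative
    cell) raise.
    """
    rs = resistant_a - both_resistant
    sr = resistant_b - both_resistant
    ss = total - both_resistant - rs - sr
    if min(both_resistant, rs, sr, ss) < 0:
        raise ValueError("marginals are inconsistent with the total")
    return Crosstab(insecticide_a=insecticide_a, insecticide_b=insecticide_b,
                    rr=both_resistant, rs=rs, sr=sr, ss=ss)
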