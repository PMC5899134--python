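"""Promoter classes and the plasmid-to-mRNA mapping.

Constitutive promoters are binned into strength classes, each assumed to
yield a fixed number of transcripts per plasmid copy in the lysate mix:
strong 30, medium 10, weak 3 mRNA per DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PromoterClass", "PROMOTERS", "mrna_concentration"]


@dataclass(frozen=True)
class PromoterClass:
    label: str
    mrna_per_dna: float

    def __post_init__(self):
        if self.mrna_per_dna <= 0:
            raise ValueError("mrna_per_dna must be > 0")


PROMOTERS = {
    "strong": PromoterClass("strong", 30.0),
    "medium": PromoterClass("medium", 10.0),
    "weak": PromoterClass("weak", 3.0),
}


def _as_promoter(promoter: PromoterClass | str) -> PromoterClass:
    if isinstance(promoter, PromoterClass):
        return promoter
    try:
        return PROMOTERS[promoter]
    except KeyError:
        raise ValueError(
            f"unknown promoter class {promoter!r}; known: {sorted(PROMOTERS)}"
        ) from None


def mrna_concentration(promoter: PromoterClass | str, plasmid_conc: float) -> float:
    """mRNA concentration (nM) from plasmid concentration and promoter class."""
    if plasmid_conc <= 0:
        raise ValueError(f"plasmid_conc must be > 0, got {plasmid_conc}")
    return _as_promoter(promoter).mrna_per_dna * plasmid_conc
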