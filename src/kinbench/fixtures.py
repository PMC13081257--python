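"""Bundled synthetic example inputs.

All fixtures are generated programmatically: an 11-member three-generation
template pedigree (55 pairwise comparisons, most of them unrelated, covering
first/second/third degree plus half-siblings and first cousins), a 12-member
variant with one closely inbred offspring, a terminal misincorporation
profile with 22% damage at position 1 of both read ends, and a uniform
allele-frequency spectrum table.
"""

from __future__ import annotations

from pathlib import Path

from .simulate import FrequencySpectrum

__all__ = [
    "PEDIGREE_11",
    "pedigree_12_inbred",
    "DAMAGE_PROFILE",
    "default_benchmark_pairs",
    "generate_fixtures",
    "FIXTURE_KINDS",
]

#: Three-generation template pedigree, 11 members / 55 pairs:
#: a grandparental couple (gp1, gp2), two sibling parents (p1, p2), three
#: unrelated spouses (sp1..sp3), three grandchildren -- c1 and h1 are
#: half-siblings through p1, c1/h1 vs c2 are first cousins -- and one
#: unrelated individual (u1).
PEDIGREE_11 = """\
# id father mother   ("0" marks a founder slot)
gp1 0 0
gp2 0 0
sp1 0 0
sp2 0 0
sp3 0 0
u1  0 0
p1  gp1 gp2
p2  gp1 gp2
c1  p1 sp1
h1  p1 sp2
c2  p2 sp3
"""

#: mating pairs available in the template for the inbred 12th member
INBRED_MATINGS = {
    "first_cousins": ("c1", "c2"),
    "half_siblings": ("c1", "h1"),
    "full_siblings": ("p1", "p2"),
}


def pedigree_12_inbred(variant: str = "first_cousins") -> str:
    """12-member pedigree (66 pairs): the template plus one offspring of a
    close-kin mating -- first cousins (default), half-siblings or full
    siblings."""
    try:
        a, b = INBRED_MATINGS[variant]
    except KeyError:
        raise ValueError(
            f"unknown inbreeding variant {variant!r}; "
            f"choose from {sorted(INBRED_MATINGS)}"
        ) from None
    return PEDIGREE_11 + f"ib1 {a} {b}\n"


#: Simplified two-column-dialect misincorporation profile: 22% terminal
#: damage decaying inward; the 1% boundary rule masks the first six
#: positions at each end.
DAMAGE_PROFILE = """\
# pos rate5 rate3
1 0.22 0.22
2 0.12 0.12
3 0.065 0.065
4 0.035 0.035
5 0.019 0.019
6 0.010 0.010
7 0.006 0.006
8 0.003 0.003
9 0.002 0.002
10 0.001 0.001
"""


def default_benchmark_pairs() -> list[tuple[str, str]]:
    """The 13 pairwise comparisons evaluated by the default benchmark on the
    template pedigree with a twin duplicate of c1: one self pair, three
    first-degree, three second-degree, two third-degree and four unrelated
    pairs."""
    return [
        ("c1", "c1.twin"),            # Self
        ("p1", "c1"), ("gp1", "p1"), ("sp3", "c2"),   # First
        ("c1", "h1"), ("gp1", "c1"), ("p2", "c1"),    # Second
        ("c1", "c2"), ("h1", "c2"),                   # Third
        ("u1", "c1"), ("sp1", "sp2"), ("gp1", "sp3"), ("u1", "gp1"),  # Unrel.
    ]


FIXTURE_KINDS = (
    "pedigree-11",
    "pedigree-12-inbred",
    "damage-profile",
    "freq-spectrum",
)


def generate_fixtures(kind: str, dest: Path, seed: int = 0,
                      n_sites: int = 10_000,
                      variant: str = "first_cousins") -> Path:
    """Write one documented fixture file under ``dest``; returns its path."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    if kind == "pedigree-11":
        path = dest / "pedigree_11.ped"
        path.write_text(PEDIGREE_11)
    elif kind == "pedigree-12-inbred":
        path = dest / f"pedigree_12_inbred_{variant}.ped"
        path.write_text(pedigree_12_inbred(variant))
    elif kind == "damage-profile":
        path = dest / "misincorporation_simple.txt"
        path.write_text(DAMAGE_PROFILE)
    elif kind == "freq-spectrum":
        path = dest / "freq_spectrum.tsv"
        spectrum = FrequencySpectrum.uniform(n_sites, seed=seed)
        path.write_text(spectrum.to_table())
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        )
    return path
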