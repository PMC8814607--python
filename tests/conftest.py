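"""Shared fixtures: quick series builders and synthetic cloning backbones."""

from __future__ import annotations

import numpy as np
import pytest

from riboreporter.design import Enzyme, load_enzymes, scan_sites
from riboreporter.plate_io import PlateLayout, SampleMeta, WellSeries

# Toy reporter ORF start: ATG, then codons chosen so that the reverse-strand
# AarI recognition (GCAGGTG on the top strand) sits at nt 13..19, which puts
# the enzyme's top-strand cut exactly after the 2nd nt of codon 2.
LUXC_PREFIX = "ATG" "AAT" "AAA" "CAA" "TGC" "AGG" "TGT"


def ws(well_id: str, lum, od, times=None, interval: float = 20.0) -> WellSeries:
    lum = np.asarray(lum, dtype=float)
    if times is None:
        times = np.arange(len(lum)) * interval
    return WellSeries(well_id=well_id, times=np.asarray(times, float), lum=lum,
                      od=np.asarray(od, dtype=float))


def triplicate(prefix: str, lum, od, interval: float = 20.0) -> list[WellSeries]:
    return [ws(f"{prefix}{i + 1}", lum, od, interval=interval) for i in range(3)]


def simple_layout(groups: dict[str, dict], blanks: list[str]) -> PlateLayout:
    wells = {}
    for group, info in groups.items():
        for well in info["wells"]:
            wells[well] = SampleMeta(
                construct=info.get("construct", "C"),
                ligand_mM=info.get("ligand_mM", 0.0),
                replicate_group=group,
            )
    for well in blanks:
        wells[well] = SampleMeta(is_blank=True)
    return PlateLayout(wells=wells)


@pytest.fixture(scope="session")
def enzymes() -> dict[str, Enzyme]:
    return load_enzymes()


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_luxc(rng: np.random.Generator, n_extra_codons: int = 12) -> str:
    """A reporter ORF starting with the fixed prefix, random codons after
    (no internal stops, so protein comparisons are unambiguous)."""
    codons = []
    while len(codons) < n_extra_codons:
        c = random_dna(rng, 3)
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    return LUXC_PREFIX + "".join(codons)


def make_fig_backbone(rng: np.random.Generator, enzymes: dict[str, Enzyme]):
    """A synthetic linear backbone with the reporter-plasmid architecture:

    filler - MCS1(CsiI,XmaJI,SacI) - promoter slot - MCS2(NcoI,SdaI,ScaI) -
    5'UTR slot - reporter ORF (with the reverse-strand AarI recognition
    inside codons 5-7) - filler.  Regenerates fillers until every enzyme
    has exactly one site.
    """
    mcs1 = "ACCAGGT" + "CCTAGG" + "GAGCTC"
    mcs2 = "CCATGG" + "CCTGCAGG" + "AGTACT"
    for _ in range(50):
        luxc = random_luxc(rng)
        parts = [
            random_dna(rng, 60),
            mcs1,
            random_dna(rng, 100),  # promoter slot
            mcs2,
            random_dna(rng, 60),  # 5'UTR slot
            luxc,
            random_dna(rng, 80),
        ]
        backbone = "".join(parts)
        luxc_start = backbone.index(luxc)
        if all(len(scan_sites(backbone, e)) == 1 for e in enzymes.values()):
            return {"backbone": backbone, "luxc": luxc, "luxc_start": luxc_start}
    raise RuntimeError("could not build a clean backbone in 50 attempts")


@pytest.fixture
def fig_backbone(enzymes):
    return make_fig_backbone(np.random.default_rng(20210915), enzymes)
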