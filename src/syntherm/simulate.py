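"""Synthetic multi-clone variant datasets with planted phenotype-linked variants.

Emulates the structure of a clone re-sequencing experiment: a handful of
phenotype-positive and -negative clones, a background of
phenotype-independent polymorphisms, and a small number of planted
variants that are fixed in the positives (mixed in designated
mixed-signature positives) and absent from the negatives. Generates
in-memory matrices and VarScan-style per-clone VCF files, plus the fixed
ten-clone / 57-variant fixture mirroring the published aggregate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .variants import GenotypeMatrix, PhenotypeLabels, VariantRecord, normalize_variant

__all__ = [
    "SimParams",
    "PlantedTruth",
    "simulate_clone_variants",
    "make_paper_fixture",
    "write_vcf_files",
    "REPLICON_LENGTHS",
]

#: approximate replicon sizes of the D. vulgaris Hildenborough genome (bp)
REPLICON_LENGTHS = {"chromosome": 3_570_858, "megaplasmid": 202_301}

_STATE_MEANS = {"present": 0.98, "absent": 0.02, "mixed": 0.5}
_EXACT_VALUES = {"present": 1.0, "absent": 0.0, "mixed": 0.5}


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Defaults mirror the study conditions: 5 syntrophy-positive clones
    plus 2 positives with mixed allele signatures at the causal loci,
    3 negatives, 55 background polymorphisms and 2 planted
    phenotype-concordant variants. ``kappa_*`` are Beta concentration
    parameters for the read-fraction noise around the fixed (~1),
    absent (~0) and mixed (~0.5) states; ``None`` means noiseless exact
    fractions. ``missing_rate`` is the probability an entry lacks
    coverage evidence entirely.
    """

    n_pos_clones: int = 5
    n_neg_clones: int = 3
    n_mixed_pos_clones: int = 2
    n_background_variants: int = 55
    n_planted: int = 2
    kappa_present: float | None = None
    kappa_absent: float | None = None
    kappa_mixed: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos_clones", "n_neg_clones", "n_mixed_pos_clones",
                     "n_background_variants", "n_planted"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("kappa_present", "kappa_absent", "kappa_mixed"):
            k = getattr(self, name)
            if k is not None and k <= 0:
                raise ValueError(f"{name} must be > 0 or None")

    @property
    def total_clones(self) -> int:
        return self.n_pos_clones + self.n_mixed_pos_clones + self.n_neg_clones


@dataclass(frozen=True)
class PlantedTruth:
    """Which variants were planted and the state intended per clone."""

    planted: tuple[VariantRecord, ...]
    intended_states: pd.DataFrame = field(compare=False)  # variants × clones


def _draw_fraction(state: str, params: SimParams, rng: np.random.Generator) -> float:
    kappa = {"present": params.kappa_present,
             "absent": params.kappa_absent,
             "mixed": params.kappa_mixed}[state]
    if kappa is None:
        return _EXACT_VALUES[state]
    mu = _STATE_MEANS[state]
    return float(np.clip(rng.beta(mu * kappa, (1.0 - mu) * kappa), 0.0, 1.0))


def _random_variant(rng: np.random.Generator, vclass: str, replicon: str,
                    taken: set[tuple[str, int]]) -> VariantRecord:
    bases = "ACGT"
    length = REPLICON_LENGTHS[replicon]
    while True:
        pos = int(rng.integers(100, length - 100))
        if (replicon, pos) in taken:
            continue
        taken.add((replicon, pos))
        break
    if vclass == "SNP":
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
    else:
        anchor = bases[rng.integers(4)]
        indel_len = int(rng.integers(1, 5))
        tail = "".join(bases[rng.integers(4)] for _ in range(indel_len))
        if rng.random() < 0.7:  # deletion
            ref, alt = anchor + tail, anchor
        else:
            ref, alt = anchor, anchor + tail
    return normalize_variant(VariantRecord(replicon, pos, ref, alt))


def _pattern_concordant(states: Mapping[str, str], positives: Sequence[str],
                        negatives: Sequence[str]) -> bool:
    """Permissive-mode concordance of an intended state pattern."""
    return (all(states[c] in ("present", "mixed") for c in positives)
            and all(states[c] == "absent" for c in negatives))


def simulate_clone_variants(params: SimParams) -> tuple[GenotypeMatrix, PhenotypeLabels, PlantedTruth]:
    """Simulate a clone panel. Planted variants are present in every
    positive (mixed in the designated mixed-signature positives) and
    absent from every negative; background variants get states drawn
    independently of phenotype, rejection-sampled away from patterns that
    would themselves be phenotype-concordant (in either label
    orientation), so planted variants are the only true signal."""
    rng = np.random.default_rng(params.seed)
    clean_pos = [f"s{i + 1}" for i in range(params.n_pos_clones)]
    mixed_pos = [f"sm{i + 1}" for i in range(params.n_mixed_pos_clones)]
    negatives = [f"ns{i + 1}" for i in range(params.n_neg_clones)]
    clones = clean_pos + mixed_pos + negatives
    positives = clean_pos + mixed_pos
    labels = PhenotypeLabels.from_sets(positives, negatives)

    taken: set[tuple[str, int]] = set()
    planted = []
    for i in range(params.n_planted):
        vclass = "SNP" if i % 2 == 0 else "INDEL"
        planted.append(_random_variant(rng, vclass, "chromosome", taken))
    background = []
    for i in range(params.n_background_variants):
        vclass = "SNP" if rng.random() < 0.5 else "INDEL"
        replicon = "chromosome" if rng.random() < 0.93 else "megaplasmid"
        background.append(_random_variant(rng, vclass, replicon, taken))

    state_rows: dict[str, dict[str, str]] = {}
    for v in planted:
        state_rows[v.key] = {**{c: "present" for c in clean_pos},
                             **{c: "mixed" for c in mixed_pos},
                             **{c: "absent" for c in negatives}}
    state_choices = np.array(["present", "mixed", "absent"])
    probs = np.array([0.3, 0.1, 0.6])
    for v in background:
        while True:
            states = {c: str(rng.choice(state_choices, p=probs)) for c in clones}
            if positives and negatives:
                if _pattern_concordant(states, positives, negatives):
                    continue
                if _pattern_concordant(states, negatives, positives):
                    continue
            break
        state_rows[v.key] = states

    variants = planted + background
    data = pd.DataFrame(np.nan, index=[v.key for v in variants], columns=clones)
    for key, states in state_rows.items():
        for clone, state in states.items():
            if params.missing_rate and rng.random() < params.missing_rate:
                continue
            data.loc[key, clone] = round(_draw_fraction(state, params, rng), 4)
    matrix = GenotypeMatrix(variants, clones, data)
    intended = pd.DataFrame(state_rows).T.reindex(index=[v.key for v in matrix.variants],
                                                  columns=clones)
    return matrix, labels, PlantedTruth(tuple(sorted(planted)), intended)


def make_paper_fixture() -> tuple[GenotypeMatrix, PhenotypeLabels]:
    """The fixed ten-clone fixture: 26 chromosome SNPs, 27 chromosome
    INDELs, 2 megaplasmid SNPs and 2 megaplasmid INDELs (57 variants),
    with the two phenotype-concordant variants at their published
    chromosome coordinates — the G→A point mutation at 3 142 197 and the
    in-frame GAG deletion at 2 381 876. Both are fully present in clones
    s1–s5, a mixed signature (fraction 0.5) in ns1–ns2, absent in
    ns3–ns5. The remaining 55 variants are distributed deterministically
    and independently of phenotype, each carried by at least one clone on
    both sides of the phenotype split (so only the planted pair is
    concordant). Per-variant fractions are constructed, not published
    data — only the aggregate counts and the concordance pattern mirror
    the study.
    """
    clones = [f"s{i}" for i in range(1, 6)] + [f"ns{i}" for i in range(1, 6)]
    positives = [f"s{i}" for i in range(1, 6)] + ["ns1", "ns2"]
    negatives = ["ns3", "ns4", "ns5"]
    labels = PhenotypeLabels.from_sets(positives, negatives)

    planted = [
        VariantRecord("chromosome", 3_142_197, "G", "A"),       # DVU3023-like SNP
        VariantRecord("chromosome", 2_381_876, "CGAG", "C"),    # in-frame GAG deletion
    ]
    rng = np.random.default_rng(20160516)  # frozen: fixture is a golden artifact
    taken = {(v.replicon, v.position) for v in planted}
    background: list[VariantRecord] = []
    for vclass, replicon, count in (("SNP", "chromosome", 25), ("INDEL", "chromosome", 26),
                                    ("SNP", "megaplasmid", 2), ("INDEL", "megaplasmid", 2)):
        for _ in range(count):
            background.append(_random_variant(rng, vclass, replicon, taken))

    variants = planted + background
    data = pd.DataFrame(np.nan, index=[v.key for v in variants], columns=clones)
    for v in planted:
        for c in clones:
            data.loc[v.key, c] = {True: 1.0, False: 0.0}[c in positives]
        data.loc[v.key, "ns1"] = 0.5
        data.loc[v.key, "ns2"] = 0.5
    for v in background:
        n_carriers = int(rng.integers(2, 9))
        carriers = set(rng.choice(clones, size=n_carriers, replace=False))
        # guarantee non-concordance in both label orientations
        if not carriers & set(negatives):
            carriers.add(negatives[int(rng.integers(len(negatives)))])
        if not carriers & set(positives):
            carriers.add(positives[int(rng.integers(len(positives)))])
        for c in clones:
            if c in carriers:
                frac = rng.uniform(0.3, 0.7) if rng.random() < 0.15 else rng.uniform(0.93, 1.0)
            else:
                frac = 0.0
            data.loc[v.key, c] = round(float(frac), 4)
    return GenotypeMatrix(variants, clones, data), labels


def write_vcf_files(matrix: GenotypeMatrix, directory: str | Path,
                    replicon_lengths: Mapping[str, int] | None = None,
                    depth: int = 100) -> list[Path]:
    """Write one VarScan-style VCF per clone (GT/DP/RD/AD/FREQ sample
    fields, FREQ as a percent string). Missing matrix entries are simply
    omitted from that clone's file, so :func:`~syntherm.variants.read_vcf_set`
    round-trips the matrix exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lengths = dict(REPLICON_LENGTHS)
    if replicon_lengths:
        lengths.update(replicon_lengths)
    replicons = sorted({v.replicon for v in matrix.variants}) or list(lengths)
    paths = []
    verbosity = pysam.set_verbosity(0)  # quiet the AD Number=1 sanity warning
    for clone in matrix.clones:
        path = directory / f"{clone}.vcf"
        header = pysam.VariantHeader()
        for rep in replicons:
            length = lengths.get(rep, max((v.position for v in matrix.variants
                                           if v.replicon == rep), default=0) + 1000)
            header.contigs.add(rep, length=length)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.formats.add("RD", 1, "Integer", "Reference-supporting read depth")
        header.formats.add("AD", 1, "Integer", "Variant-supporting read depth")
        header.formats.add("FREQ", 1, "String", "Variant allele frequency (percent)")
        header.add_sample(clone)
        try:
            out = pysam.VariantFile(str(path), "w", header=header)
        except OSError as exc:
            raise OSError(f"cannot write VCF {path}: {exc}") from exc
        with out:
            for var in matrix.variants:
                frac = matrix.fractions.loc[var.key, clone]
                if pd.isna(frac):
                    continue
                rec = out.new_record(contig=var.replicon, start=var.position - 1,
                                     alleles=(var.ref, var.alt))
                rec.filter.add("PASS")
                ad = int(round(frac * depth))
                sample = rec.samples[clone]
                sample["GT"] = (1, 1) if frac >= 0.75 else ((0, 1) if frac > 0 else (0, 0))
                sample["DP"] = depth
                sample["RD"] = depth - ad
                sample["AD"] = ad
                sample["FREQ"] = f"{frac * 100:.4f}%"
                out.write(rec)
        paths.append(path)
    pysam.set_verbosity(verbosity)
    return paths
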