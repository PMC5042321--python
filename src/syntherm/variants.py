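"""Multi-clone variant matrix construction and phenotype-concordance screen.

Per-clone VCFs (VarScan-dialect FREQ percent strings, or standard AD/DP)
are merged into a variants × clones matrix of alternate-allele read
fractions. The screen asks which variants are present in every
phenotype-positive clone and absent from every negative clone —
tolerating, in permissive mode, clones that carry a mixed signature of
alleles at the locus. Minimal effect annotation (reading-frame of an
indel, codon-level consequence on a supplied CDS) covers what the
screen's hits need; full functional annotation is out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "PhenotypeLabels",
    "ScreenResult",
    "normalize_variant",
    "read_vcf_set",
    "classify_allele_state",
    "concordance_screen",
    "annotate_indel_frame",
    "codon_effect",
    "summarize_variant_counts",
    "DEFAULT_THRESHOLDS",
]

#: (t_absent, t_present): fraction ≤ 0.1 → absent, ≥ 0.9 → present, between → mixed.
#: Inferred defaults — the underlying read-fraction heatmap convention is not
#: published; both are configurable on every entry point.
DEFAULT_THRESHOLDS = (0.1, 0.9)

_BASES = re.compile(r"^[ACGTN]+$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One called variant: replicon, 1-based position, REF and ALT alleles."""

    replicon: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be ≥ 1 (1-based VCF coordinates)")
        for allele in (self.ref, self.alt):
            if not allele or not _BASES.match(allele):
                raise ValueError(f"invalid allele {allele!r}")

    @property
    def vclass(self) -> str:
        """SNP iff both alleles are single bases, else INDEL."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> str:
        return f"{self.replicon}:{self.position}:{self.ref}>{self.alt}"


def normalize_variant(v: VariantRecord) -> VariantRecord:
    """Parsimony-normalise an allele pair: strip the shared suffix, then
    the shared prefix (advancing POS), always keeping ≥ 1 base per
    allele. Unifies padded/anchored representations of the same indel;
    reference-free, so repeat-mediated left-shifting is not attempted."""
    ref, alt, pos = v.ref.upper(), v.alt.upper(), v.position
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantRecord(v.replicon, pos, ref, alt)


class GenotypeMatrix:
    """Variants × clones matrix of alternate-allele read fractions.

    Fractions live in [0, 1]; NaN marks entries with no coverage
    evidence. Rows are keyed by ``VariantRecord.key`` and kept in
    (replicon, position, ref, alt) order.
    """

    def __init__(self, variants: Sequence[VariantRecord], clones: Sequence[str],
                 fractions: pd.DataFrame) -> None:
        variants = sorted(variants)
        keys = [v.key for v in variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variants")
        if len(set(clones)) != len(clones):
            raise ValueError("duplicate clone ids")
        frac = fractions.reindex(index=keys, columns=list(clones)).astype(float)
        bad = frac.stack(future_stack=True).dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("allele fractions must lie in [0, 1]")
        self.variants = list(variants)
        self.clones = list(clones)
        self.fractions = frac

    def variant_by_key(self, key: str) -> VariantRecord:
        for v in self.variants:
            if v.key == key:
                return v
        raise KeyError(key)

    def equals(self, other: "GenotypeMatrix", tol: float = 1e-6) -> bool:
        if [v.key for v in self.variants] != [v.key for v in other.variants]:
            return False
        if set(self.clones) != set(other.clones):
            return False
        a = self.fractions
        b = other.fractions[a.columns]
        both_nan = a.isna() & b.isna()
        close = (a - b).abs() <= tol
        return bool((both_nan | close).all().all())

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({len(self.variants)} variants × {len(self.clones)} clones)"


class PhenotypeLabels(dict):
    """clone id → 'positive' (co-culturable) or 'negative'."""

    def __init__(self, mapping: Mapping[str, str]) -> None:
        for clone, lab in mapping.items():
            if lab not in ("positive", "negative"):
                raise ValueError(f"label for {clone!r} must be positive/negative, got {lab!r}")
        super().__init__(mapping)

    @classmethod
    def from_sets(cls, positives: Iterable[str], negatives: Iterable[str]) -> "PhenotypeLabels":
        return cls({**{c: "positive" for c in positives},
                    **{c: "negative" for c in negatives}})

    def positives(self) -> list[str]:
        return [c for c, lab in self.items() if lab == "positive"]

    def negatives(self) -> list[str]:
        return [c for c, lab in self.items() if lab == "negative"]


@dataclass(frozen=True)
class ScreenResult:
    candidates: tuple[VariantRecord, ...]
    states: pd.DataFrame = field(compare=False)  # variants × clones state calls
    mode: str = "permissive"


# ---------------------------------------------------------------------------
# VCF input

def _fraction_from_sample(sample, file_label: str) -> float | None:
    """Alternate-allele fraction for one sample record: VarScan FREQ
    percent string preferred, AD/DP fallback. None when uncallable."""
    freq = sample.get("FREQ") if "FREQ" in sample else None
    if freq not in (None, "."):
        text = freq[0] if isinstance(freq, tuple) else freq
        if isinstance(text, bytes):
            text = text.decode()
        try:
            return float(str(text).rstrip("%")) / 100.0
        except ValueError as exc:
            raise ValueError(f"{file_label}: unparseable FREQ value {text!r}") from exc
    ad = sample.get("AD") if "AD" in sample else None
    dp = sample.get("DP") if "DP" in sample else None
    if ad is None or dp in (None, 0):
        return None
    if isinstance(ad, tuple):  # standard Number=R: (ref_depth, alt_depth, ...)
        alt_depth = ad[1] if len(ad) > 1 else ad[0]
    else:  # VarScan Number=1: alt depth only
        alt_depth = ad
    if alt_depth is None:
        return None
    return min(float(alt_depth) / float(dp), 1.0)


def read_vcf_set(paths: Sequence[str | Path],
                 clone_ids: Sequence[str] | None = None) -> GenotypeMatrix:
    """Merge per-clone VCFs into a :class:`GenotypeMatrix`.

    Variants are unified across files by (replicon, position, ref, alt)
    after parsimony normalisation. A record present with coverage but no
    alternate support yields fraction 0; a site entirely absent from a
    clone's file carries no coverage evidence and stays missing (NaN).
    ``clone_ids`` overrides header sample names (single-sample files
    only); duplicate clone ids are an error.
    """
    paths = [Path(p) for p in paths]
    if clone_ids is not None and len(clone_ids) != len(paths):
        raise ValueError("clone_ids must match paths one-to-one")
    # htslib warns about the (deliberate) VarScan-style AD Number=1 header
    verbosity = pysam.set_verbosity(0)
    try:
        per_clone = _collect_calls(paths, clone_ids)
    finally:
        pysam.set_verbosity(verbosity)
    clones = list(per_clone)
    variants = sorted({v for calls in per_clone.values() for v in calls})
    data = pd.DataFrame(np.nan, index=[v.key for v in variants], columns=clones)
    for clone, calls in per_clone.items():
        for var, frac in calls.items():
            data.loc[var.key, clone] = frac
    return GenotypeMatrix(variants, clones, data)


def _collect_calls(paths: list[Path], clone_ids: Sequence[str] | None
                   ) -> dict[str, dict[VariantRecord, float]]:
    per_clone: dict[str, dict[VariantRecord, float]] = {}
    for i, path in enumerate(paths):
        try:
            vf = pysam.VariantFile(str(path))
        except (OSError, ValueError) as exc:
            raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
        with vf:
            samples = list(vf.header.samples)
            if clone_ids is not None:
                if len(samples) != 1:
                    raise ValueError(f"{path}: clone_ids override requires single-sample files")
                samples = [(clone_ids[i], vf.header.samples[0])]
            else:
                samples = [(s, s) for s in samples]
            for clone, _ in samples:
                if clone in per_clone:
                    raise ValueError(f"duplicate clone id {clone!r} (file {path})")
                per_clone[clone] = {}
            for line_no, rec in enumerate(vf, start=1):
                if rec.alts is None:
                    continue
                for alt in rec.alts:
                    try:
                        var = normalize_variant(
                            VariantRecord(rec.chrom, rec.pos, rec.ref, alt))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path} record {line_no} ({rec.chrom}:{rec.pos}): {exc}") from exc
                    for clone, sample_name in samples:
                        frac = _fraction_from_sample(rec.samples[sample_name],
                                                     f"{path} record {line_no}")
                        if frac is not None:
                            per_clone[clone][var] = frac
    return per_clone


# ---------------------------------------------------------------------------
# screening

def classify_allele_state(fraction: float,
                          thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Call present / absent / mixed / missing from a read fraction."""
    t_absent, t_present = thresholds
    if not (0.0 <= t_absent < t_present <= 1.0):
        raise ValueError(f"thresholds must satisfy 0 ≤ t_absent < t_present ≤ 1, got {thresholds}")
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return "missing"
    if fraction >= t_present:
        return "present"
    if fraction <= t_absent:
        return "absent"
    return "mixed"


def concordance_screen(matrix: GenotypeMatrix, labels: PhenotypeLabels,
                       mode: str = "permissive",
                       thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> ScreenResult:
    """Select variants concordant with the phenotype.

    A candidate is present in every positive clone and absent in every
    negative clone. ``permissive`` lets a mixed signature in a positive
    clone count as presence (heterogeneous colony picks or multiple
    genome copies can dilute the allele without negating it); ``strict``
    demands a clean call everywhere. Missing entries disqualify in both
    modes. Candidate order follows the matrix's genomic order; clone
    order never matters.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"mode must be strict or permissive, got {mode!r}")
    missing = [c for c in matrix.clones if c not in labels]
    if missing:
        raise ValueError(f"clones without phenotype label: {missing}")
    pos = [c for c in matrix.clones if labels[c] == "positive"]
    neg = [c for c in matrix.clones if labels[c] == "negative"]
    if not pos or not neg:
        raise ValueError("screen needs at least one positive and one negative clone")

    states = matrix.fractions.map(lambda f: classify_allele_state(f, thresholds))
    ok_positive = {"present", "mixed"} if mode == "permissive" else {"present"}
    candidates = []
    for var in matrix.variants:
        row = states.loc[var.key]
        if all(row[c] in ok_positive for c in pos) and all(row[c] == "absent" for c in neg):
            candidates.append(var)
    return ScreenResult(tuple(candidates), states, mode)


def summarize_variant_counts(matrix: GenotypeMatrix) -> dict:
    """Counts by replicon × variant class, plus the grand total."""
    by: dict[str, dict[str, int]] = {}
    for v in matrix.variants:
        by.setdefault(v.replicon, {"SNP": 0, "INDEL": 0})[v.vclass] += 1
    return {"by_replicon": by, "total": len(matrix.variants)}


# ---------------------------------------------------------------------------
# effect annotation

def annotate_indel_frame(variant: VariantRecord) -> str:
    """'in-frame' when the indel length is a multiple of 3, else 'frameshift'."""
    if variant.vclass != "INDEL":
        raise ValueError(f"{variant.key} is a SNP, not an INDEL")
    return "in-frame" if (len(variant.ref) - len(variant.alt)) % 3 == 0 else "frameshift"


def codon_effect(cds_sequence: str, cds_offset: int,
                 variant: VariantRecord) -> tuple[list[str], list[str], str]:
    """Codon-level consequence of a variant on a coding sequence.

    ``cds_offset`` is the 0-based offset of the variant's first REF base
    within ``cds_sequence`` (sense strand, frame starting at offset 0).
    Returns (reference codons touched, codons after the edit in the same
    window, note). A TGA codon lost from the window is flagged: in-frame
    removal of a TGA can either truncate the product (stop) or exchange
    a selenocysteine residue, so it is called out explicitly.
    """
    cds = cds_sequence.upper()
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if cds_offset < 0 or cds_offset + len(ref) > len(cds):
        raise ValueError("variant falls outside the supplied CDS")
    if cds[cds_offset:cds_offset + len(ref)] != ref:
        raise ValueError(
            f"REF allele {ref!r} does not match CDS at offset {cds_offset} "
            f"(found {cds[cds_offset:cds_offset + len(ref)]!r})")
    start = (cds_offset // 3) * 3
    end = -((cds_offset + len(ref)) // -3) * 3  # ceil to codon boundary
    edited_window = cds[start:cds_offset] + alt + cds[cds_offset + len(ref):end]
    ref_codons = [cds[i:i + 3] for i in range(start, end, 3)]
    alt_codons = [edited_window[i:i + 3] for i in range(0, len(edited_window) - len(edited_window) % 3, 3)]

    shift = (len(alt) - len(ref)) % 3
    if shift != 0:
        note = "frameshift"
    elif "TGA" in ref_codons and "TGA" not in alt_codons:
        note = ("TGA codon replaced: stop read-through or "
                "selenocysteine residue exchanged")
    elif len(ref) == len(alt) == 1:
        aa_ref = str(Seq(ref_codons[0]).translate())
        aa_alt = str(Seq(alt_codons[0]).translate())
        if aa_ref == aa_alt:
            note = "synonymous"
        elif aa_alt == "*":
            note = f"nonsense ({aa_ref}→stop)"
        else:
            note = f"missense ({aa_ref}→{aa_alt})"
    elif len(ref) > len(alt):
        note = "in-frame deletion"
    else:
        note = "in-frame insertion"
    return ref_codons, alt_codons, note
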