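"""Functional MHC distances from amino-acid physico-chemical descriptors.

The β-subunit exon 2 of MHC class IIB genes encodes the peptide-binding
region; alleles that differ chemically at these positions present
different peptide repertoires. Functional distance between two residues
is the Euclidean distance in five-dimensional z-descriptor space;
between two alleles, the mean of the residue distances over the aligned
sequence; within a genotype, the distance between the carried allele
copies (diversity); and between two individuals, the maximum (or mean)
distance over cross-individual allele-copy pairs.

Loci are named ``Ocle-DAB1`` and ``Ocle-DAB2`` after the two storm-petrel
class IIB genes, but nothing restricts the machinery to two loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .dyads import DyadMatrix
from .zscales import STANDARD_RESIDUES, validate_descriptor_table, z_descriptor_table

DAB1 = "Ocle-DAB1"
DAB2 = "Ocle-DAB2"
LOCI = (DAB1, DAB2)

_RES_INDEX = {r: k for k, r in enumerate(STANDARD_RESIDUES)}


@dataclass(frozen=True)
class Allele:
    """An MHC allele: identifier, locus, amino-acid sequence."""

    id: str
    locus: str
    sequence: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.sequence) - set(STANDARD_RESIDUES))
        if bad:
            raise ValueError(
                f"allele {self.id}: non-standard residue symbol(s) {bad} "
                "(ambiguity codes and gaps are not supported)"
            )


@dataclass
class Genotype:
    """An individual's diploid genotype over one or more loci.

    ``alleles`` maps locus -> pair of Allele (two copies, possibly
    identical). ``breeding_status`` is sample_day - hatch_day in days:
    larger (less negative) values are later in incubation.
    """

    individual: str
    alleles: dict[str, tuple[Allele, Allele]]
    sex: str | None = None
    breeding_status: float | None = None
    sample_day: float | None = None
    hatch_day: float | None = None

    def copies(self, loci: Sequence[str]) -> list[Allele]:
        out: list[Allele] = []
        for locus in loci:
            if locus not in self.alleles:
                raise KeyError(f"individual {self.individual}: missing locus {locus}")
            pair = self.alleles[locus]
            if len(pair) != 2:
                raise ValueError(f"individual {self.individual}: need 2 copies at {locus}")
            out.extend(pair)
        return out


def _loci_for_mode(locus_mode: str) -> tuple[str, ...]:
    mode = locus_mode.lower().replace("ocle-", "")
    if mode == "dab1":
        return (DAB1,)
    if mode == "dab2":
        return (DAB2,)
    if mode == "both":
        return LOCI
    raise ValueError(f"unknown locus_mode {locus_mode!r}; expected DAB1, DAB2 or both")


# ---------------------------------------------------------------------
# residue- and allele-level distances


def aa_distance(a: str, b: str, table: pd.DataFrame | None = None) -> float:
    """Euclidean distance between two residues in z-descriptor space."""
    table = z_descriptor_table() if table is None else validate_descriptor_table(table)
    for sym in (a, b):
        if sym not in table.index:
            raise ValueError(f"unknown residue symbol {sym!r}")
    diff = table.loc[a].to_numpy() - table.loc[b].to_numpy()
    return float(np.sqrt(np.sum(diff**2)))


def aa_distance_matrix(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """20x20 matrix of pairwise residue distances."""
    table = z_descriptor_table() if table is None else validate_descriptor_table(table)
    z = table.to_numpy()
    d = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_RES_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from None


def allele_distance(
    a: Allele | str,
    b: Allele | str,
    table: pd.DataFrame | None = None,
    position_mask: Sequence[int] | None = None,
) -> float:
    """Mean positionwise residue distance between two aligned alleles.

    ``position_mask`` restricts the average to a subset of 0-based
    positions (e.g. peptide-binding-region sites only).
    """
    sa = a.sequence if isinstance(a, Allele) else a
    sb = b.sequence if isinstance(b, Allele) else b
    if len(sa) != len(sb):
        raise ValueError(f"allele length mismatch: {len(sa)} vs {len(sb)}")
    dmat = aa_distance_matrix(table).to_numpy()
    ia, ib = _encode(sa), _encode(sb)
    if position_mask is not None:
        mask = np.asarray(position_mask, dtype=np.intp)
        if mask.size == 0:
            raise ValueError("position_mask must select at least one position")
        ia, ib = ia[mask], ib[mask]
    return float(dmat[ia, ib].mean())


class _AlleleDistanceCache:
    """Pairwise allele-distance lookup over a fixed allele universe."""

    def __init__(self, alleles: Iterable[Allele], table: pd.DataFrame | None = None,
                 position_mask: Sequence[int] | None = None) -> None:
        self._dmat = aa_distance_matrix(table).to_numpy()
        self._mask = None if position_mask is None else np.asarray(position_mask, dtype=np.intp)
        self._enc: dict[str, np.ndarray] = {}
        self._cache: dict[tuple[str, str], float] = {}
        for al in alleles:
            self.add(al)

    def add(self, allele: Allele) -> None:
        if allele.id not in self._enc:
            enc = _encode(allele.sequence)
            self._enc[allele.id] = enc if self._mask is None else enc[self._mask]

    def dist(self, a: Allele, b: Allele) -> float:
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        hit = self._cache.get(key)
        if hit is None:
            ea, eb = self._enc[a.id], self._enc[b.id]
            if ea.shape != eb.shape:
                raise ValueError(f"allele length mismatch: {a.id} vs {b.id}")
            hit = float(self._dmat[ea, eb].mean())
            self._cache[key] = hit
        return hit


def allele_distance_frame(
    alleles: Sequence[Allele], table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Square symmetric functional-distance matrix over an allele set."""
    cache = _AlleleDistanceCache(alleles, table)
    n = len(alleles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cache.dist(alleles[i], alleles[j])
    ids = [a.id for a in alleles]
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------
# genotype-level measures


def genotype_diversity(
    g: Genotype,
    locus_mode: str = "both",
    combine: str = "mean",
    table: pd.DataFrame | None = None,
    _cache: "_AlleleDistanceCache | None" = None,
) -> float:
    """Functional diversity of one genotype.

    Per-locus mode: the distance between the two carried copies
    (homozygotes score 0). Both-loci mode: ``combine`` (mean or max)
    over all unordered pairs of the four carried copies.
    """
    loci = _loci_for_mode(locus_mode)
    copies = g.copies(loci)
    cache = _cache if _cache is not None else _AlleleDistanceCache(copies, table)
    dists = [cache.dist(a, b) for a, b in itertools.combinations(copies, 2)]
    if combine == "mean":
        return float(np.mean(dists))
    if combine == "max":
        return float(np.max(dists))
    raise ValueError(f"unknown combine rule {combine!r}")


def dyad_mhc_distance(
    gi: Genotype,
    gj: Genotype,
    locus_mode: str = "both",
    rule: str = "max",
    table: pd.DataFrame | None = None,
    _cache: "_AlleleDistanceCache | None" = None,
) -> float:
    """Pairwise MHC distance between two individuals.

    Default rule takes the maximum functional distance over all
    locus-matched cross-individual allele-copy pairs (i's copies at a
    locus against j's copies at the same locus, pooled over the
    requested loci); low values mean the dyad shares functionally
    similar genotypes, and identical genotypes score 0. ``rule='mean'``
    is the sensitivity alternative.
    """
    loci = _loci_for_mode(locus_mode)
    all_copies = gi.copies(loci) + gj.copies(loci)
    cache = _cache if _cache is not None else _AlleleDistanceCache(all_copies, table)
    dists = [cache.dist(a, b)
             for locus in loci
             for a in gi.copies([locus]) for b in gj.copies([locus])]
    if rule == "max":
        return float(np.max(dists))
    if rule == "mean":
        return float(np.mean(dists))
    raise ValueError(f"unknown dyad rule {rule!r}")


def build_mhc_matrices(
    genotypes: Sequence[Genotype],
    locus_mode: str = "both",
    rule: str = "max",
    table: pd.DataFrame | None = None,
) -> dict[str, DyadMatrix]:
    """FF / MM square and MF rectangular MHC distance matrices.

    Individuals keep their input order within each sex; MF rows are
    males, columns females (same orientation as the chemical matrices).
    """
    loci = _loci_for_mode(locus_mode)
    all_copies = [c for g in genotypes for c in g.copies(loci)]
    cache = _AlleleDistanceCache(all_copies, table)

    for g in genotypes:
        if g.sex not in {"F", "M"}:
            raise ValueError(f"individual {g.individual}: unknown sex label {g.sex!r}")
    females = [g for g in genotypes if g.sex == "F"]
    males = [g for g in genotypes if g.sex == "M"]

    def square(group: list[Genotype]) -> DyadMatrix:
        n = len(group)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = dyad_mhc_distance(group[i], group[j], locus_mode, rule, _cache=cache)
                vals[i, j] = vals[j, i] = d
        return DyadMatrix.square(vals, [g.individual for g in group])

    mf = np.zeros((len(males), len(females)))
    for i, gm in enumerate(males):
        for j, gf in enumerate(females):
            mf[i, j] = dyad_mhc_distance(gm, gf, locus_mode, rule, _cache=cache)

    return {
        "FF": square(females),
        "MM": square(males),
        "MF": DyadMatrix.rect(mf, [g.individual for g in males], [g.individual for g in females]),
    }


# ---------------------------------------------------------------------
# heterozygosity utilities


def mhc_heterozygosity(g: Genotype, locus: str, mode: str = "indicator",
                       table: pd.DataFrame | None = None) -> float:
    """Per-locus MHC heterozygosity.

    ``indicator`` (default): 0 if the two copies have identical
    sequences, else 1. ``functional``: the functional distance between
    the two copies.
    """
    a, b = g.alleles[locus]
    if mode == "indicator":
        return float(a.sequence != b.sequence)
    if mode == "functional":
        return allele_distance(a, b, table)
    raise ValueError(f"unknown heterozygosity mode {mode!r}")


def heterozygosity_correlation(mhc_het: Sequence[float], genome_het: Sequence[float]) -> float:
    """Pearson correlation of MHC vs genome-wide heterozygosity.

    Genome-wide values are consumed as given (e.g. from RAD-seq
    pipelines upstream). Zero variance in either vector makes the
    correlation undefined and raises.
    """
    x = np.asarray(mhc_het, dtype=float)
    y = np.asarray(genome_het, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input vector")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------
# sequence input


def translate_cds(nucleotides: str, frame: int = 0) -> str:
    """Translate a coding-strand nucleotide fragment (standard code).

    ``frame`` is the 0-based offset of the first codon; trailing partial
    codons are dropped. A premature stop codon is an error — exon 2
    fragments of expressed alleles must be open.
    """
    if frame not in (0, 1, 2):
        raise ValueError("reading frame must be 0, 1 or 2")
    seq = nucleotides[frame:]
    seq = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(seq).translate())
    if "*" in aa:
        raise ValueError("premature stop codon in coding sequence")
    return aa


def read_allele_fasta(
    path: str | Path,
    alphabet: str = "aa",
    frame: int = 0,
    locus_from_id: bool = True,
) -> list[Allele]:
    """Read alleles from FASTA (amino-acid, or nucleotide to translate).

    With ``locus_from_id`` the locus is the record-id prefix before
    ``*`` (e.g. ``Ocle-DAB1*03`` -> locus ``Ocle-DAB1``).
    """
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "nt":
            seq = translate_cds(seq, frame)
        elif alphabet != "aa":
            raise ValueError("alphabet must be 'aa' or 'nt'")
        locus = rec.id.split("*")[0] if locus_from_id else ""
        alleles.append(Allele(id=rec.id, locus=locus, sequence=seq))
    return alleles


def write_allele_fasta(alleles: Sequence[Allele], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alleles:
            fh.write(f">{a.id}\n{a.sequence}\n")


def read_genotype_table(
    path: str | Path, alleles: Sequence[Allele]
) -> list[Genotype]:
    """Read a TSV genotype table into Genotype objects.

    Expected columns: ``individual, sex, sample_day, hatch_day,
    DAB1_1, DAB1_2, DAB2_1, DAB2_2`` where allele columns hold allele
    ids present in ``alleles``.
    """
    pool = {a.id: a for a in alleles}
    tab = pd.read_csv(path, sep="\t", dtype={"individual": str})
    out = []
    for _, row in tab.iterrows():
        try:
            geno = {
                DAB1: (pool[row["DAB1_1"]], pool[row["DAB1_2"]]),
                DAB2: (pool[row["DAB2_1"]], pool[row["DAB2_2"]]),
            }
        except KeyError as exc:
            raise ValueError(
                f"individual {row['individual']}: allele id {exc.args[0]!r} not in FASTA"
            ) from None
        status = float(row["sample_day"]) - float(row["hatch_day"])
        out.append(
            Genotype(
                individual=str(row["individual"]),
                alleles=geno,
                sex=str(row["sex"]),
                breeding_status=status,
                sample_day=float(row["sample_day"]),
                hatch_day=float(row["hatch_day"]),
            )
        )
    return out
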