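"""Synthetic mixed-tissue RNA-seq generator.

Emulates the data-generating process behind a dissected-tissue knockdown
experiment: a target tissue made of neuron-like cells (fraction ``phi``)
and glia-like cells (``1 - phi``), contaminated by an adjacent tissue at
a library-specific fraction ``c``, with a cell-type-restricted knockdown
of one ubiquitously expressed gene (residual ratio ``r`` applied in
neuron-like cells only). Per-gene fragment counts are negative binomial
(variance ``mu + alpha * mu**2``); raw paired reads carry 5' composition
bias over the first sequencing cycles, PCR duplicates at a rate that
decays with nominal cDNA input, and small fractions of QC-failing reads
(N-containing, homopolymer, low mean quality). An optional
double-stranded shRNA transgene emits reads from the 3' targeted half of
the knockdown target.

Every emitted read has a ground-truth alignment record and a category
label, so downstream filters and counters can be validated exactly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as qio
from .core import AlignmentRecord, CountMatrix, GeneModel, ReadPair

logger = logging.getLogger(__name__)

CLASSES = ("neuronal", "glial", "contaminant_specific", "ubiquitous")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: cDNA-to-duplicate-rate defaults: rate = DUP_MAX * exp(-DUP_DECAY * ng),
#: placing nominal inputs of 2-6 ng in the 0.40-0.73 range seen in
#: low-input pilot libraries.
DUP_MAX = 0.986
DUP_DECAY = 0.150


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment."""

    n_genes: int = 60
    class_proportions: dict = field(
        default_factory=lambda: {
            "neuronal": 0.30,
            "glial": 0.10,
            "contaminant_specific": 0.15,
            "ubiquitous": 0.45,
        }
    )
    phi: float = 0.5  # neuron-like cell fraction of the target tissue
    knockdown_ratio: float = 0.2  # residual target expression where active
    knockdown_mode: str = "cell_restricted"  # or "somatic"
    contamination: tuple = (0.6, 0.6, 0.0, 0.0, 0.6, 0.0, 0.0)
    groups: tuple = ("WT", "WT", "WT", "WT", "KD", "KD", "KD")
    labels: tuple = ()
    cdna_input: tuple = (5.0, 2.0, 4.0, 3.0, 2.0, 6.0, 4.0)
    dispersion: float = 0.1
    library_size: int = 3000
    dup_max: float = DUP_MAX
    dup_decay: float = DUP_DECAY
    bias_amplitude: float = 0.5
    bias_positions: int = 10
    bias_profile: dict | None = None  # {1-based position: {base: multiplier}}
    read_length: int = 100
    fragment_length: int = 300  # mean insert size (random fragmentation)
    fragment_length_sd: float = 30.0
    frac_n: float = 0.002
    frac_homopolymer: float = 0.001
    frac_lowqual: float = 0.004
    frac_five_prime_lowqual: float = 0.08
    shrna: bool = False
    shrna_level: float = 9.0
    response_fraction: float = 0.3
    response_log2fc: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.labels:
            tally: dict[str, int] = {}
            labels = []
            for g in self.groups:
                tally[g] = tally.get(g, 0) + 1
                labels.append(f"{g}_{tally[g]}")
            self.labels = tuple(labels)
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(self.class_proportions) != set(CLASSES):
            raise ValueError(f"class proportions must cover {CLASSES}")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must be in (0, 1)")
        if not 0.0 <= self.knockdown_ratio <= 1.0:
            raise ValueError("knockdown_ratio must be in [0, 1]")
        if self.knockdown_mode not in ("cell_restricted", "somatic"):
            raise ValueError("knockdown_mode must be cell_restricted or somatic")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.read_length <= 10:
            raise ValueError("read_length must be > 10")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        if self.fragment_length_sd < 0:
            raise ValueError("fragment_length_sd must be >= 0")
        n_lib = len(self.groups)
        if not (len(self.contamination) == len(self.cdna_input) == n_lib):
            raise ValueError("per-library arrays must have equal length")
        for c in self.contamination:
            if not 0.0 <= c < 1.0:
                raise ValueError("contamination fractions must be in [0, 1)")
        for frac in (
            self.frac_n,
            self.frac_homopolymer,
            self.frac_lowqual,
            self.frac_five_prime_lowqual,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("read-class fractions must be in [0, 1]")

    # deterministic class layout: contiguous blocks in fixed class order
    def class_counts(self) -> dict[str, int]:
        raw = {k: self.class_proportions[k] * self.n_genes for k in CLASSES}
        counts = {k: max(1, int(np.floor(v))) for k, v in raw.items()}
        counts["ubiquitous"] = max(2, counts["ubiquitous"])  # control + target
        while sum(counts.values()) < self.n_genes:
            k = max(CLASSES, key=lambda k: raw[k] - counts[k])
            counts[k] += 1
        while sum(counts.values()) > self.n_genes:
            k = min(CLASSES, key=lambda k: raw[k] - counts[k])
            if counts[k] > (2 if k == "ubiquitous" else 1):
                counts[k] -= 1
        return counts

    def gene_classes(self) -> list[str]:
        counts = self.class_counts()
        out: list[str] = []
        for k in CLASSES:
            out.extend([k] * counts[k])
        return out

    def marker_roles(self) -> dict[str, str]:
        """Role -> gene id, from the deterministic class layout."""
        classes = self.gene_classes()
        ids = [f"g{i + 1:04d}" for i in range(self.n_genes)]
        first = {k: ids[classes.index(k)] for k in CLASSES}
        ubi = [g for g, k in zip(ids, classes) if k == "ubiquitous"]
        return {
            "neuron_marker": first["neuronal"],
            "glia_marker": first["glial"],
            "contaminant_marker": first["contaminant_specific"],
            "ubiquitous_control": ubi[0],
            "knockdown_target": ubi[1],
            "transgene": "transgene",
        }

    def bias_probs(self) -> np.ndarray:
        """Per-cycle base probabilities (bias_positions x ACGT)."""
        P = self.bias_positions
        probs = np.full((P, 4), 0.25)
        if self.bias_profile is not None:
            for p in range(1, P + 1):
                mult = self.bias_profile.get(p) or self.bias_profile.get(str(p)) or {}
                w = np.array([float(mult.get(b, 1.0)) for b in "ACGT"])
                probs[p - 1] = w / w.sum()
        elif self.bias_amplitude > 0:
            for p in range(P):
                w = np.ones(4)
                w["ACGT".index("ACGT"[p % 4])] += 3.0 * self.bias_amplitude
                probs[p] = w / w.sum()
        return probs

    def duplicate_fraction(self, cdna_input: float) -> float:
        """Expected PCR-duplicate fraction, monotone decreasing in input."""
        return min(0.95, self.dup_max * float(np.exp(-self.dup_decay * cdna_input)))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("contamination", "groups", "labels", "cdna_input"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TissueProfiles:
    """Per-gene baseline abundance in each cellular compartment.

    Units are arbitrary transcripts-per-cell; each compartment vector is
    normalized to the same total so that marker FPKM is linear in the
    contamination fraction under the mixing model.
    """

    gene_ids: list[str]
    gene_class: list[str]
    neuron: np.ndarray
    glia: np.ndarray
    contaminant: np.ndarray
    roles: dict[str, str]
    response_log2fc: np.ndarray

    def __post_init__(self) -> None:
        idx = self.index()
        neu, tg = idx[self.roles["neuron_marker"]], idx[self.roles["transgene"]]
        gli = idx[self.roles["glia_marker"]]
        con = idx[self.roles["contaminant_marker"]]
        tgt = idx[self.roles["knockdown_target"]]
        for i in (neu, tg):
            if self.glia[i] != 0 or self.contaminant[i] != 0:
                raise ValueError("neuron marker/transgene must be neuron-restricted")
        if self.neuron[gli] != 0 or self.contaminant[gli] != 0:
            raise ValueError("glia marker must be glia-restricted")
        target_mix = 0.5 * (self.neuron[con] + self.glia[con])
        if self.contaminant[con] < 5 * max(target_mix, 1e-12):
            raise ValueError("contaminant marker must be strongly tissue-enriched")
        if min(self.neuron[tgt], self.glia[tgt], self.contaminant[tgt]) <= 0:
            raise ValueError("knockdown target must be expressed everywhere")

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def build_profiles(config: SimulationConfig) -> TissueProfiles:
    rng = np.random.default_rng([config.seed, 1])
    classes = config.gene_classes() + ["transgene"]
    ids = [f"g{i + 1:04d}" for i in range(config.n_genes)] + ["transgene"]
    n = len(ids)
    neuron = np.zeros(n)
    glia = np.zeros(n)
    contam = np.zeros(n)
    base = rng.lognormal(mean=0.8, sigma=0.8, size=n)
    for i, k in enumerate(classes):
        v = base[i]
        if k == "neuronal":
            neuron[i] = v
        elif k == "glial":
            glia[i] = v
        elif k == "contaminant_specific":
            contam[i] = v
            neuron[i] = glia[i] = 0.05 * v
        elif k == "ubiquitous":
            neuron[i] = glia[i] = contam[i] = v
    roles = config.marker_roles()
    idx = {g: i for i, g in enumerate(ids)}
    neuron[idx[roles["neuron_marker"]]] = 8.0
    glia[idx[roles["neuron_marker"]]] = contam[idx[roles["neuron_marker"]]] = 0.0
    glia[idx[roles["glia_marker"]]] = 8.0
    neuron[idx[roles["glia_marker"]]] = contam[idx[roles["glia_marker"]]] = 0.0
    con = idx[roles["contaminant_marker"]]
    neuron[con] = glia[con] = 0.3
    contam[con] = 10.0
    for role in ("ubiquitous_control", "knockdown_target"):
        i = idx[roles[role]]
        neuron[i] = glia[i] = contam[i] = 3.0
    t = idx["transgene"]
    neuron[t], glia[t], contam[t] = 5.0, 0.0, 0.0

    # knockdown-response genes: a fraction of each endogenous class shifts
    # expression (random sign, fixed log2 magnitude) in compartments where
    # the knockdown is active
    response = np.zeros(n)
    marker_ids = set(roles.values())
    for k in ("neuronal", "glial", "ubiquitous"):
        members = [i for i, c in enumerate(classes) if c == k and ids[i] not in marker_ids]
        n_resp = int(round(config.response_fraction * len(members)))
        chosen = rng.choice(members, size=n_resp, replace=False) if n_resp else []
        for i in chosen:
            response[i] = config.response_log2fc * (1 if rng.random() < 0.5 else -1)

    # one common scale for the target-tissue compartments (so ubiquitous
    # genes keep equal per-cell abundance in neurons and glia and the
    # bulk knockdown fold change is exactly phi*r + (1-phi)), and the
    # same mixture total for the contaminant tissue (so marker FPKM is
    # linear in the contamination fraction)
    s_target = 100.0 / (config.phi * neuron + (1.0 - config.phi) * glia).sum()
    neuron *= s_target
    glia *= s_target
    contam *= 100.0 / contam.sum()
    return TissueProfiles(ids, classes, neuron, glia, contam, roles, response)


def mixture_abundance(
    profiles: TissueProfiles,
    phi: float,
    c: float,
    r: float,
    knockdown_mode: str = "cell_restricted",
) -> np.ndarray:
    """Expected bulk abundance under the tissue-mixing model.

    ``a(g) = (1-c) * [phi * neuron(g) * k(g) + (1-phi) * glia(g)]
             + c * contaminant(g)`` with ``k = r`` for the knockdown
    target (extended to all compartments in somatic mode). Knockdown
    response effects apply wherever the knockdown is active (``r < 1``).
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must be in (0, 1)")
    if not 0.0 <= c < 1.0:
        raise ValueError("c must be in [0, 1)")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    neuron = profiles.neuron.copy()
    glia = profiles.glia.copy()
    contam = profiles.contaminant.copy()
    tgt = profiles.index()[profiles.roles["knockdown_target"]]
    somatic = knockdown_mode == "somatic"
    if r < 1.0:
        fx = np.exp2(profiles.response_log2fc)
        neuron *= fx
        if somatic:
            glia *= fx
            contam *= fx
        neuron[tgt] *= r
        if somatic:
            glia[tgt] *= r
            contam[tgt] *= r
    return (1.0 - c) * (phi * neuron + (1.0 - phi) * glia) + c * contam


def simulate_counts(
    abundances: np.ndarray,
    library_size: int,
    alpha: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one library's per-gene fragment counts.

    Counts are NB with mean ``mu_g = library_size * a_g / sum(a)`` and
    variance ``mu + alpha * mu**2`` (Poisson when ``alpha == 0``).
    """
    if alpha < 0:
        raise ValueError("dispersion alpha must be >= 0")
    abundances = np.asarray(abundances, dtype=float)
    if (abundances < 0).any():
        raise ValueError("abundances must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu = library_size * abundances / abundances.sum()
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


# ------------------------------------------------------------- annotation
def build_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random non-overlapping gene loci on two references, plus the
    transgene on its own reference (the transgene is quantified against
    its own sequence). Deterministic for a fixed seed."""
    rng = np.random.default_rng([config.seed, 0])
    target_id = config.marker_roles()["knockdown_target"]
    genes: list[GeneModel] = []
    cursors = {"ref_1": 0, "ref_2": 0}
    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        ref = "ref_1" if i % 2 == 0 else "ref_2"
        start = cursors[ref] + int(rng.integers(200, 501))
        if gid == target_id:
            # fixed two-exon layout so the 3' shRNA-homologous half is a
            # clean transcript-coordinate interval
            lengths, introns = [800, 800], [150]
        else:
            n_exon = int(rng.integers(1, 6))
            lengths = [int(rng.integers(400, 801))] + [
                int(rng.integers(350, 801)) for _ in range(n_exon - 1)
            ]
            introns = [int(rng.integers(60, 401)) for _ in range(n_exon - 1)]
        exons, pos = [], start
        for j, ln in enumerate(lengths):
            exons.append((pos, pos + ln))
            pos += ln + (introns[j] if j < len(introns) else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gid, ref, strand, exons))
        cursors[ref] = exons[-1][1]
    genes.append(GeneModel("transgene", "transgene_ref", "+", [(100, 1600)]))
    cursors["transgene_ref"] = 1700
    refs = {
        name: "".join(rng.choice(list("ACGT"), size=cursors[name] + 200))
        for name in ("ref_1", "ref_2", "transgene_ref")
    }
    return refs, genes


# ------------------------------------------------------------------- reads
class _Transcript:
    """Spliced-sequence view of a gene with cycle-accurate placement."""

    def __init__(self, gene: GeneModel, refs: dict[str, str]):
        self.gene = gene
        ref = refs[gene.reference]
        self.seq = "".join(ref[s:e] for s, e in gene.union_exons)
        self.length = len(self.seq)
        self.bounds = []  # cumulative exon end offsets
        off = 0
        for s, e in gene.union_exons:
            off += e - s
            self.bounds.append(off)

    def _single_exon(self, t_start: int, length: int) -> bool:
        i = bisect_right(self.bounds, t_start)
        return t_start + length <= self.bounds[i]

    def place(
        self,
        rng: np.random.Generator,
        frag_len: int,
        read_len: int,
        region: tuple[int, int] | None = None,
    ) -> int | None:
        """Uniform fragment start on the transcript, rejection-sampled so
        each mate sits inside one exon (single-M truth alignments)."""
        lo, hi = (0, self.length) if region is None else region
        hi = hi - frag_len
        if hi < lo:
            return None
        for _ in range(100):
            t = int(rng.integers(lo, hi + 1))
            if self._single_exon(t, read_len) and self._single_exon(
                t + frag_len - read_len, read_len
            ):
                return t
        # fall back to a fully intra-exon placement
        prev = 0
        candidates = []
        for b in self.bounds:
            if b - prev >= frag_len and b > lo and prev < hi + frag_len:
                candidates.append((max(prev, lo), min(b, hi + frag_len)))
            prev = b
        if not candidates:
            return None
        s, e = candidates[int(rng.integers(len(candidates)))]
        return int(rng.integers(s, e - frag_len + 1))


@dataclass
class LibraryReads:
    """Raw reads plus ground truth for one simulated library."""

    name: str
    group: str
    cdna_input: float
    pairs: list[ReadPair]
    alignments: list[AlignmentRecord]
    labels: pd.DataFrame  # read_id, gene, category


def _mate_records(
    read_id: str,
    transcript: _Transcript,
    t_start: int,
    frag_len: int,
    read_len: int,
    quals: tuple[np.ndarray, np.ndarray],
    swap: bool,
) -> tuple[list[AlignmentRecord], tuple[str, str]]:
    gene = transcript.gene
    seq_fwd = transcript.seq[t_start : t_start + read_len]
    seq_rev = revcomp(transcript.seq[t_start + frag_len - read_len : t_start + frag_len])
    gA = gene.transcript_to_genome(t_start)
    gB = gene.transcript_to_genome(t_start + frag_len - read_len)
    specs = [(seq_fwd, gA, "+"), (seq_rev, gB, "-")]
    if swap:
        specs.reverse()
    recs = []
    for mate, (seq, gstart, strand) in enumerate(specs, start=1):
        other = specs[2 - mate]
        recs.append(
            AlignmentRecord(
                read_id=read_id,
                mate=mate,
                reference=gene.reference,
                start=gstart,
                strand=strand,
                length=read_len,
                mapq=60,
                mate_reference=gene.reference,
                mate_start=other[1],
                qual_sum=int(quals[mate - 1].sum()),
            )
        )
    return recs, (specs[0][0], specs[1][0])


def simulate_library_reads(
    counts: np.ndarray,
    gene_ids: list[str],
    genes: list[GeneModel],
    refs: dict[str, str],
    config: SimulationConfig,
    library: str,
    group: str,
    cdna_input: float,
    rng: np.random.Generator,
    duplicate_fraction: float | None = None,
) -> LibraryReads:
    """Emit paired reads with artifacts and truth records for one library."""
    rl, fl = config.read_length, config.fragment_length
    by_id = {g.gene_id: g for g in genes}
    transcripts: dict[str, _Transcript] = {}
    bias = config.bias_probs() if (config.bias_amplitude > 0 or config.bias_profile) else None
    bias_cum = np.cumsum(bias, axis=1) if bias is not None else None
    target_id = config.marker_roles()["knockdown_target"]

    pairs: list[ReadPair] = []
    alignments: list[AlignmentRecord] = []
    labels: list[tuple[str, str, str]] = []
    clean_index: list[int] = []  # indices into `pairs` eligible for duplication
    recs_of: dict[str, list[AlignmentRecord]] = {}
    gene_of: dict[str, str] = {}
    skipped: set[str] = set()

    def transcript(gid: str) -> _Transcript:
        if gid not in transcripts:
            transcripts[gid] = _Transcript(by_id[gid], refs)
        return transcripts[gid]

    def baseline_quals() -> np.ndarray:
        return np.full(rl, 37 + int(rng.integers(-2, 3)), dtype=np.int64)

    def apply_bias(seq: str) -> str:
        if bias_cum is None:
            return seq
        u = rng.random(config.bias_positions)
        prefix = "".join(
            "ACGT"[int(np.searchsorted(bias_cum[p], u[p]))]
            for p in range(config.bias_positions)
        )
        return prefix + seq[config.bias_positions :]

    def emit(
        gid: str,
        category: str,
        region: tuple[int, int] | None = None,
        mutate=None,
        biased: bool = True,
    ) -> bool:
        tr = transcript(gid)
        if tr.length < fl:
            if gid not in skipped:
                logger.warning(
                    "gene %s transcript (%d bp) shorter than fragment length %d; skipped",
                    gid, tr.length, fl,
                )
                skipped.add(gid)
            return False
        sd = config.fragment_length_sd
        flen = fl if sd == 0 else int(round(rng.normal(fl, sd)))
        flen = int(np.clip(flen, max(rl, fl - 3 * sd), min(fl + 3 * sd, tr.length)))
        t = tr.place(rng, flen, rl, region)
        if t is None:
            return False
        rid = f"{library}:{len(pairs) + 1:07d}"
        q1, q2 = baseline_quals(), baseline_quals()
        swap = bool(rng.random() < 0.5)
        recs, (s1, s2) = _mate_records(rid, tr, t, flen, rl, (q1, q2), swap)
        if biased:
            s1, s2 = apply_bias(s1), apply_bias(s2)
        pair = ReadPair(rid, s1, q1, s2, q2)
        if mutate is not None:
            pair = mutate(pair)
            for rec, q in zip(recs, (pair.quals1, pair.quals2)):
                rec.qual_sum = int(q.sum())
        pairs.append(pair)
        alignments.extend(recs)
        labels.append((rid, gid, category))
        recs_of[rid] = recs
        gene_of[rid] = gid
        return True

    # unique clean fragments: these ARE the simulated counts
    for gid, k in zip(gene_ids, counts):
        for _ in range(int(k)):
            if emit(gid, "unique"):
                clean_index.append(len(pairs) - 1)

    # shRNA transgene reads from the 3' targeted half of the target gene
    if config.shrna and group == "KD":
        tr = transcript(target_id)
        region = (tr.length // 2, tr.length)
        n_target = int(counts[gene_ids.index(target_id)])
        for _ in range(int(round(config.shrna_level * n_target))):
            emit(target_id, "shrna", region=region)

    # PCR duplicates: whole-pair copies of clean fragments
    d = (
        config.duplicate_fraction(cdna_input)
        if duplicate_fraction is None
        else duplicate_fraction
    )
    n_dup = int(round(len(clean_index) * d / (1.0 - d))) if d > 0 else 0
    for _ in range(n_dup):
        src = pairs[clean_index[int(rng.integers(len(clean_index)))]]
        rid = f"{library}:{len(pairs) + 1:07d}"
        pairs.append(ReadPair(rid, src.bases1, src.quals1.copy(), src.bases2, src.quals2.copy()))
        for rec in recs_of[src.id]:
            alignments.append(dataclasses.replace(rec, read_id=rid))
        labels.append((rid, gene_of[src.id], "duplicate"))

    # QC-failing classes, deterministic corruption patterns
    p_abund = counts / counts.sum() if counts.sum() else None

    def random_gene() -> str:
        if p_abund is None:
            return gene_ids[int(rng.integers(len(gene_ids)))]
        return gene_ids[int(rng.choice(len(gene_ids), p=p_abund))]

    n_total = len(clean_index)

    def corrupt_n(p: ReadPair) -> ReadPair:
        b = list(p.bases1)
        b[rl // 2] = "N"
        return ReadPair(p.id, "".join(b), p.quals1, p.bases2, p.quals2)

    def corrupt_homopolymer(p: ReadPair) -> ReadPair:
        run = max(60, rl // 2)
        b = p.bases1[:10] + "A" * run + p.bases1[10 + run :]
        return ReadPair(p.id, b[:rl], p.quals1, p.bases2, p.quals2)

    def corrupt_lowqual(p: ReadPair) -> ReadPair:
        return ReadPair(p.id, p.bases1, np.full(rl, 20), p.bases2, np.full(rl, 20))

    def degrade_five_prime(p: ReadPair) -> ReadPair:
        q = np.full(rl, 33)
        q[:10] = 2
        return ReadPair(p.id, p.bases1, q.copy(), p.bases2, q.copy())

    for frac, cat, fn in (
        (config.frac_n, "corrupt_n", corrupt_n),
        (config.frac_homopolymer, "corrupt_homopolymer", corrupt_homopolymer),
        (config.frac_lowqual, "corrupt_lowqual", corrupt_lowqual),
        (config.frac_five_prime_lowqual, "five_prime_lowqual", degrade_five_prime),
    ):
        for _ in range(int(round(frac * n_total))):
            emit(random_gene(), cat, mutate=fn)

    df = pd.DataFrame(labels, columns=["read_id", "gene", "category"])
    df.insert(0, "library", library)
    return LibraryReads(library, group, cdna_input, pairs, alignments, df)


# -------------------------------------------------------------- experiment
@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    profiles: TissueProfiles
    refs: dict[str, str]
    genes: list[GeneModel]
    counts: CountMatrix  # unique clean fragments per gene per library
    libraries: list[LibraryReads]

    @property
    def target_gene(self) -> str:
        return self.profiles.roles["knockdown_target"]

    def targeted_region(self) -> tuple[int, int]:
        """3' shRNA-homologous half of the target, transcript coordinates."""
        gene = next(g for g in self.genes if g.gene_id == self.target_gene)
        L = gene.union_length
        return (L // 2, L)

    def write(self, outdir: str) -> None:
        qio.ensure_dir(outdir)
        qio.write_fasta(self.refs, os.path.join(outdir, "genome.fa"))
        qio.write_gtf(self.genes, os.path.join(outdir, "annotation.gtf"))
        self.counts.counts.to_csv(os.path.join(outdir, "true_counts.tsv"), sep="\t")
        self.counts.meta.to_csv(os.path.join(outdir, "libraries.tsv"), sep="\t")
        self.config.to_json(os.path.join(outdir, "config.json"))
        prof = pd.DataFrame(
            {
                "gene": self.profiles.gene_ids,
                "class": self.profiles.gene_class,
                "neuron": self.profiles.neuron,
                "glia": self.profiles.glia,
                "contaminant": self.profiles.contaminant,
                "response_log2fc": self.profiles.response_log2fc,
            }
        )
        prof.to_csv(os.path.join(outdir, "profiles.tsv"), sep="\t", index=False)
        ref_lengths = {k: len(v) for k, v in self.refs.items()}
        for lib in self.libraries:
            qio.write_fastq_pair(
                lib.pairs,
                os.path.join(outdir, f"{lib.name}_R1.fastq"),
                os.path.join(outdir, f"{lib.name}_R2.fastq"),
            )
            seqs = {}
            for p in lib.pairs:
                seqs[(p.id, 1)] = (p.bases1, "".join(chr(q + 33) for q in p.quals1))
                seqs[(p.id, 2)] = (p.bases2, "".join(chr(q + 33) for q in p.quals2))
            qio.write_sam(
                [(r, *seqs[(r.read_id, r.mate)]) for r in lib.alignments],
                ref_lengths,
                os.path.join(outdir, f"{lib.name}.truth.sam"),
            )
            lib.labels.to_csv(
                os.path.join(outdir, f"{lib.name}.labels.tsv"), sep="\t", index=False
            )


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the full generator: annotation, profiles, counts, reads."""
    refs, genes = build_annotation(config)
    profiles = build_profiles(config)
    cols = {}
    libraries = []
    for j, (label, group, c, ng) in enumerate(
        zip(config.labels, config.groups, config.contamination, config.cdna_input)
    ):
        r = config.knockdown_ratio if group == "KD" else 1.0
        a = mixture_abundance(profiles, config.phi, c, r, config.knockdown_mode)
        counts = simulate_counts(
            a, config.library_size, config.dispersion, np.random.default_rng([config.seed, 2, j])
        )
        cols[label] = counts
        libraries.append(
            simulate_library_reads(
                counts,
                profiles.gene_ids,
                genes,
                refs,
                config,
                label,
                group,
                ng,
                np.random.default_rng([config.seed, 3, j]),
            )
        )
    counts_df = pd.DataFrame(cols, index=profiles.gene_ids)
    meta = pd.DataFrame(
        {
            "group": list(config.groups),
            "cdna_input": list(config.cdna_input),
            "contamination": list(config.contamination),
            "seed": config.seed,
        },
        index=list(config.labels),
    )
    return SimulatedExperiment(
        config, profiles, refs, genes, CountMatrix(counts_df, meta), libraries
    )
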