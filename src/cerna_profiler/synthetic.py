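"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes: a
four-condition FPKM matrix (Sham, PD, NLID, LID by default) in which a
chosen set of genes follows a given model shape on the log2 scale while
background genes stay flat; transcript and miRNA sequences carrying
planted perfect 6mer seed sites; and genomic neighborhoods with
controlled gaps for cis-target testing.  Everything is a pure function of
(design, seed): the same seed gives bit-identical outputs.

Noise is lognormal — normal on the log2 scale — because profile
clustering operates on log2 ratios; this keeps planted shapes unbiased
after the transform.  Background sequences are rejection-sampled until
they are free of every miRNA's seed site, so negatives are clean by
construction (a retry cap guards against impossible designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import ExpressionMatrix, MiRNARecord
from .cerna import seed_match

__all__ = [
    "DEFAULT_CONDITIONS",
    "PlantedProfile",
    "SyntheticDesign",
    "SyntheticTruth",
    "generate_expression",
    "generate_sequences",
    "generate_annotation",
    "generate_cerna_instance",
    "generate_ct_table",
    "generate_transcript_panel",
]

DEFAULT_CONDITIONS = ("Sham", "PD", "NLID", "LID")
_BASES = np.array(list("ACGT"))
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PlantedProfile:
    """A group of genes planted on one model shape."""

    shape: tuple[int, ...]
    n_genes: int
    base_expression: float = 10.0  # FPKM at the reference condition
    noise_sd: float = 0.2  # log2-scale replicate noise


@dataclass
class SyntheticDesign:
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    n_background_genes: int = 1000
    planted: list[PlantedProfile] = field(default_factory=list)
    background_base: float = 10.0
    background_noise_sd: float | None = None  # None -> same as first planted group
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if self.replicates_per_condition < 1 or self.n_background_genes < 0:
            raise ValueError("counts must be non-negative (replicates >= 1)")
        for p in self.planted:
            if len(p.shape) != len(self.conditions):
                raise ValueError(
                    f"shape {p.shape} incompatible with "
                    f"{len(self.conditions)} conditions"
                )
            if p.n_genes < 0 or p.base_expression <= 0 or p.noise_sd < 0:
                raise ValueError("invalid planted group parameters")


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating, keyed for test harnesses."""

    profile_of_gene: dict[str, tuple[int, ...]] = field(default_factory=dict)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)
    cis_pairs: dict[tuple[str, str], int] = field(default_factory=dict)
    non_cis_pairs: dict[tuple[str, str], int] = field(default_factory=dict)
    lncrna_candidacy: dict[str, bool] = field(default_factory=dict)
    seed_offsets: dict[tuple[str, str], int] = field(default_factory=dict)


def generate_expression(design: SyntheticDesign) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """FPKM matrix with planted shapes over flat background.

    A planted gene's replicate value in condition t is
    ``base * 2**(shape_t + N(0, noise_sd))``; with ``noise_sd = 0`` the
    condition means are exactly ``base * 2**shape_t``.  Background genes
    are flat with the same lognormal noise.
    """
    rng = np.random.default_rng(design.rng_seed)
    n_cond = len(design.conditions)
    n_rep = design.replicates_per_condition
    sample_ids = [
        f"{cond}_r{r + 1}" for cond in design.conditions for r in range(n_rep)
    ]
    condition_of_sample = {
        s: s.rsplit("_r", 1)[0] for s in sample_ids
    }
    truth = SyntheticTruth()
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for p_idx, group in enumerate(design.planted):
        shape = np.repeat(np.asarray(group.shape, dtype=float), n_rep)
        for g in range(group.n_genes):
            gid = f"planted{p_idx}_g{g:04d}"
            eps = rng.normal(0.0, group.noise_sd, size=n_cond * n_rep)
            rows.append(group.base_expression * 2.0 ** (shape + eps))
            gene_ids.append(gid)
            truth.profile_of_gene[gid] = tuple(group.shape)
    bg_sd = design.background_noise_sd
    if bg_sd is None:
        bg_sd = design.planted[0].noise_sd if design.planted else 0.0
    flat = tuple(0 for _ in design.conditions)
    for g in range(design.n_background_genes):
        gid = f"bg_g{g:05d}"
        eps = rng.normal(0.0, bg_sd, size=n_cond * n_rep)
        rows.append(design.background_base * 2.0 ** eps)
        gene_ids.append(gid)
        truth.profile_of_gene[gid] = flat
    values = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        condition_of_sample=condition_of_sample,
        condition_order=list(design.conditions),
        values=values,
    )
    return matrix, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _has_any_site(seq: str, mirnas: list[MiRNARecord]) -> bool:
    return any(seed_match(m, seq).n_sites > 0 for m in mirnas)


def _clean_seq(
    rng: np.random.Generator,
    length: int,
    mirnas: list[MiRNARecord],
    max_retries: int,
) -> str:
    for _ in range(max_retries):
        seq = _random_seq(rng, length)
        if not _has_any_site(seq, mirnas):
            return seq
    raise RuntimeError(
        f"could not sample a {length}-nt sequence free of all "
        f"{len(mirnas)} seed sites within {max_retries} retries"
    )


def generate_sequences(
    n_lncrnas: int,
    n_mrnas: int,
    n_mirnas: int,
    planted_triplets: int,
    seq_length: int = 500,
    rng_seed: int = 0,
    mirna_length: int = 22,
    max_retries: int = 1000,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], dict[str, str], list[MiRNARecord], SyntheticTruth]:
    """Transcript and miRNA sequences with planted perfect 6mer seed sites.

    Triplet i couples lncRNA i, miRNA i and mRNA i: the exact reverse
    complement of miRNA i's seed (positions 2-7) is inserted at a recorded
    offset in both member sequences.  Every sequence is otherwise screened
    to carry no seed site of any miRNA in the set, so non-planted
    (lncRNA, miRNA, mRNA) combinations share no site.  With ``out_dir``
    the sequences are also written as FASTA (lncrnas.fa, mrnas.fa,
    mirnas.fa).
    """
    if planted_triplets > min(n_lncrnas, n_mrnas, n_mirnas):
        raise ValueError("more planted triplets than available molecules")
    if seq_length < 30:
        raise ValueError("seq_length must be >= 30")
    rng = np.random.default_rng(rng_seed)

    mirnas: list[MiRNARecord] = []
    seeds_seen: set[str] = set()
    for i in range(n_mirnas):
        for _ in range(max_retries):
            seq = _random_seq(rng, mirna_length).replace("T", "U")
            seed = seq[1:7]
            if seed not in seeds_seen:
                seeds_seen.add(seed)
                mirnas.append(MiRNARecord(f"mir{i:03d}", seq))
                break
        else:
            raise RuntimeError("could not sample miRNAs with distinct seeds")

    truth = SyntheticTruth()

    def planted_seq(mirna: MiRNARecord, tid: str) -> str:
        site = mirna.sequence[1:7].replace("U", "T").translate(_DNA_COMPLEMENT)[::-1]
        for _ in range(max_retries):
            backbone = _clean_seq(rng, seq_length - 6, mirnas, max_retries)
            offset = int(rng.integers(0, len(backbone) + 1))
            seq = backbone[:offset] + site + backbone[offset:]
            # insertion can create junction sites for other miRNAs; re-check
            ok = all(
                seed_match(m, seq).n_sites == (1 if m.mirna_id == mirna.mirna_id else 0)
                for m in mirnas
            )
            if ok:
                truth.seed_offsets[(mirna.mirna_id, tid)] = offset
                return seq
        raise RuntimeError(f"could not plant a clean site for {tid}")

    lnc_seqs: dict[str, str] = {}
    mrna_seqs: dict[str, str] = {}
    for i in range(n_lncrnas):
        tid = f"lnc{i:03d}"
        if i < planted_triplets:
            lnc_seqs[tid] = planted_seq(mirnas[i], tid)
        else:
            lnc_seqs[tid] = _clean_seq(rng, seq_length, mirnas, max_retries)
    for i in range(n_mrnas):
        tid = f"mrna{i:03d}"
        if i < planted_triplets:
            mrna_seqs[tid] = planted_seq(mirnas[i], tid)
        else:
            mrna_seqs[tid] = _clean_seq(rng, seq_length, mirnas, max_retries)
    for i in range(planted_triplets):
        truth.triplets.append((f"lnc{i:03d}", f"mir{i:03d}", f"mrna{i:03d}"))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, entries in [
            ("lncrnas.fa", lnc_seqs.items()),
            ("mrnas.fa", mrna_seqs.items()),
            ("mirnas.fa", [(m.mirna_id, m.sequence) for m in mirnas]),
        ]:
            with open(out / name, "w") as fh:
                for sid, seq in entries:
                    fh.write(f">{sid}\n{seq}\n")
    return lnc_seqs, mrna_seqs, mirnas, truth


def generate_annotation(
    n_pairs_within_10kb: int,
    n_pairs_beyond: int,
    chrom_length: int = 10_000_000,
    rng_seed: int = 0,
    window_bp: int = 10_000,
    transcript_length: int = 1_000,
    out_path: str | Path | None = None,
) -> tuple[list[str], SyntheticTruth]:
    """GTF lines for lncRNA/gene pairs with controlled genomic gaps.

    Cis pairs get a gap <= ``window_bp``; non-cis pairs a gap in
    (window_bp, 2*window_bp].  Successive pairs are separated by more than
    2*window_bp so no cross-pair hit can arise.  Returns the GTF lines
    (optionally written to ``out_path``) and the truth with recorded gaps.
    """
    rng = np.random.default_rng(rng_seed)
    truth = SyntheticTruth()
    lines: list[str] = []
    cursor = 1
    separation = 2 * window_bp + 1

    def emit(tid: str, gid: str, start: int, kind: str) -> int:
        end = start + transcript_length - 1
        mid = start + transcript_length // 2
        attrs = f'gene_id "{gid}"; transcript_id "{tid}"; biotype "{kind}";'
        lines.append(f"chr1\tsynthetic\ttranscript\t{start}\t{end}\t.\t+\t.\t{attrs}")
        lines.append(f"chr1\tsynthetic\texon\t{start}\t{mid - 1}\t.\t+\t.\t{attrs}")
        lines.append(f"chr1\tsynthetic\texon\t{mid + 1}\t{end}\t.\t+\t.\t{attrs}")
        return end

    pair_specs = [(True, i) for i in range(n_pairs_within_10kb)] + [
        (False, i) for i in range(n_pairs_beyond)
    ]
    for is_cis, i in pair_specs:
        tag = "cis" if is_cis else "far"
        lnc_id = f"lnc_{tag}{i:03d}"
        gene_id = f"gene_{tag}{i:03d}"
        if is_cis:
            gap = int(rng.integers(0, window_bp + 1))
        else:
            gap = int(rng.integers(window_bp + 1, 2 * window_bp + 1))
        lnc_end = emit(lnc_id, lnc_id, cursor, "novel")
        gene_start = lnc_end + gap + 1
        gene_end = emit(gene_id, gene_id, gene_start, "known_coding")
        if is_cis:
            truth.cis_pairs[(lnc_id, gene_id)] = gap
        else:
            truth.non_cis_pairs[(lnc_id, gene_id)] = gap
        cursor = gene_end + separation
    if cursor - 1 > chrom_length:
        raise ValueError(
            f"chrom_length {chrom_length} too short; need {cursor - 1} bp"
        )
    if out_path is not None:
        Path(out_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return lines, truth


def generate_cerna_instance(
    n_triplets: int = 5,
    n_lncrnas: int = 20,
    n_mrnas: int = 25,
    n_extra_mirnas: int = 3,
    n_samples: int = 12,
    seq_length: int = 500,
    rng_seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str], list[MiRNARecord], SyntheticTruth]:
    """A complete ceRNA test instance: expression plus sequences.

    Each planted triplet's lncRNA and mRNA receive an identical
    (noise-free) expression series, so their correlation is exactly the
    pairwise maximum; all other genes get independent random series.  The
    sequences come from :func:`generate_sequences`, so only planted
    triplets share seed sites.
    """
    lnc_seqs, mrna_seqs, mirnas, truth = generate_sequences(
        n_lncrnas,
        n_mrnas,
        n_mirnas=n_triplets + n_extra_mirnas,
        planted_triplets=n_triplets,
        seq_length=seq_length,
        rng_seed=rng_seed,
    )
    rng = np.random.default_rng(rng_seed + 1)
    gene_ids = list(lnc_seqs) + list(mrna_seqs)
    values = rng.lognormal(mean=2.0, sigma=0.8, size=(len(gene_ids), n_samples))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for lnc, _, mrna in truth.triplets:
        values[idx[mrna]] = values[idx[lnc]]  # identical series -> r = 1
    n_cond = 4
    rep = n_samples // n_cond
    if rep * n_cond != n_samples:
        raise ValueError("n_samples must be divisible by 4")
    sample_ids = [f"{c}_r{r + 1}" for c in DEFAULT_CONDITIONS for r in range(rep)]
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        condition_of_sample={s: s.rsplit("_r", 1)[0] for s in sample_ids},
        condition_order=list(DEFAULT_CONDITIONS),
        values=values,
    )
    sequences = {**lnc_seqs, **mrna_seqs}
    return matrix, sequences, mirnas, truth


def generate_ct_table(
    target_gene: str = "Nonratt023402-like",
    reference_gene: str = "GAPDH",
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    log2_drop_per_condition: tuple[float, ...] = (0.0, 1.0, 1.0, 2.0),
    n_samples_per_condition: int = 6,
    n_replicates: int = 3,
    base_target_ct: float = 25.0,
    base_reference_ct: float = 18.0,
    ct_sd: float = 0.1,
    rng_seed: int = 0,
):
    """Synthetic qPCR plate emulating a target falling across conditions.

    A 1-unit log2 drop in expression raises the target Ct by 1 cycle, so
    the expected relative quantity in condition t is
    ``2**-log2_drop_per_condition[t]`` against the first condition.
    Returns a :class:`~cerna_profiler.qpcr.CtTable`.
    """
    from .qpcr import CtRow, CtTable

    if len(log2_drop_per_condition) != len(conditions):
        raise ValueError("one log2 drop per condition required")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for cond, drop in zip(conditions, log2_drop_per_condition):
        for s in range(n_samples_per_condition):
            sid = f"{cond}_animal{s + 1}"
            t_ct = base_target_ct + drop
            for gene, base in [(target_gene, t_ct), (reference_gene, base_reference_ct)]:
                reps = list(base + rng.normal(0.0, ct_sd, size=n_replicates))
                rows.append(CtRow(sid, cond, gene, [float(x) for x in reps]))
    return CtTable(rows)


def generate_transcript_panel(rng_seed: int = 0):
    """A small novel-transcript panel exercising every lncRNA filter rule.

    Returns ``(records, evidence)``: six transcripts, one failing each
    rule (length, exon count, ORF length, CPC, CNCI-like score, Pfam)
    and one clean candidate passing everything.
    """
    from .core_io import TranscriptRecord
    from .lncrna import CodingEvidence

    rng = np.random.default_rng(rng_seed)

    def seq(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    def rec(tid: str, n_exons: int, length: int, sequence: str) -> TranscriptRecord:
        per = length // n_exons
        exons, pos = [], 1001
        for i in range(n_exons):
            ln = per if i < n_exons - 1 else length - per * (n_exons - 1)
            exons.append((pos, pos + ln - 1))
            pos += ln + 100
        return TranscriptRecord(
            tid, tid, "chr2", "+", (exons[0][0], exons[-1][1]), exons, sequence, "novel"
        )

    panel, evidence = [], {}
    panel.append(rec("novel_pass", 2, 500, seq(500)))
    evidence["novel_pass"] = CodingEvidence(-1.2, -0.8, False)
    panel.append(rec("novel_short", 2, 150, seq(150)))
    evidence["novel_short"] = CodingEvidence(-1.0, -1.0, False)
    panel.append(rec("novel_monoexonic", 1, 400, seq(400)))
    evidence["novel_monoexonic"] = CodingEvidence(-1.0, -1.0, False)
    body = seq(600)
    orf = "ATG" + "GCA" * 132 + "TAA"  # 402 nt, over the 300-nt rule
    s = body[:100] + orf + body[100 + len(orf):]
    panel.append(rec("novel_coding_orf", 2, 600, s))
    evidence["novel_coding_orf"] = CodingEvidence(-1.0, -1.0, False)
    panel.append(rec("novel_cpc_positive", 3, 450, seq(450)))
    evidence["novel_cpc_positive"] = CodingEvidence(0.7, -0.5, False)
    panel.append(rec("novel_pfam_hit", 2, 450, seq(450)))
    evidence["novel_pfam_hit"] = CodingEvidence(-0.4, -0.9, True)
    return panel, evidence
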