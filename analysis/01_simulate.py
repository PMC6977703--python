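#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Emits, under results/synthetic/: a four-condition FPKM matrix with 50
genes planted on the monotone-decreasing shape (Sham > PD ~ NLID > LID)
among 1,000 flat genes; lncRNA/mRNA/miRNA FASTA files with 5 planted
ceRNA triplets; a GTF with 6 cis and 4 non-cis lncRNA/gene pairs; a qPCR
plate for a falling target gene with per-animal dyskinesia (AIM) scores;
and a truth.json recording everything that was planted.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cerna_profiler import write_expression_matrix
from cerna_profiler.pipeline import DECREASING_SHAPE
from cerna_profiler import synthetic


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    design = synthetic.SyntheticDesign(
        planted=[synthetic.PlantedProfile(DECREASING_SHAPE, n_genes=50, noise_sd=0.2)],
        n_background_genes=1000,
        rng_seed=args.seed,
    )
    matrix, etruth = synthetic.generate_expression(design)
    write_expression_matrix(matrix, out / "expression.tsv")
    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.condition_of_sample[s]}\n")

    cmatrix, sequences, mirnas, ctruth = synthetic.generate_cerna_instance(
        rng_seed=args.seed + 202
    )
    write_expression_matrix(cmatrix, out / "cerna_expression.tsv")
    with open(out / "lncrnas.fa", "w") as fh:
        for g in cmatrix.gene_ids:
            if g.startswith("lnc"):
                fh.write(f">{g}\n{sequences[g]}\n")
    with open(out / "mrnas.fa", "w") as fh:
        for g in cmatrix.gene_ids:
            if g.startswith("mrna"):
                fh.write(f">{g}\n{sequences[g]}\n")
    with open(out / "mirnas.fa", "w") as fh:
        for m in mirnas:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")

    gtf_lines, atruth = synthetic.generate_annotation(
        n_pairs_within_10kb=6, n_pairs_beyond=4, rng_seed=args.seed + 303
    )
    (out / "annotation.gtf").write_text("\n".join(gtf_lines) + "\n")

    # qPCR plate: 11 animals per condition (the correlation sample size),
    # target falling 1, 1 and 2 log2 units below Sham in PD, NLID and LID
    ct = synthetic.generate_ct_table(
        n_samples_per_condition=11, rng_seed=args.seed + 404
    )
    with open(out / "ct_table.tsv", "w") as fh:
        fh.write("sample_id\tcondition\tgene\tct\n")
        for row in ct.rows:
            for well in row.ct_replicates:
                fh.write(f"{row.sample_id}\t{row.condition}\t{row.gene}\t{well:.6f}\n")
    # per-LID-animal AIM scores generated from each animal's realized
    # target-vs-reference Ct gap, so expression and score co-vary
    rng = np.random.default_rng(args.seed + 505)
    aim = {}
    for row in ct.rows:
        if row.condition == "LID" and row.gene != "GAPDH":
            ref = next(
                r for r in ct.rows
                if r.sample_id == row.sample_id and r.gene == "GAPDH"
            )
            dct = row.mean_ct - ref.mean_ct
            aim[row.sample_id] = round(4.0 + 2.0 * (dct - 7.0) + rng.normal(0, 0.15), 3)
    with open(out / "aim_scores.tsv", "w") as fh:
        fh.write("sample_id\taim_score\n")
        for sid, score in aim.items():
            fh.write(f"{sid}\t{score}\n")

    truth = {
        "planted_shape": list(DECREASING_SHAPE),
        "planted_profile_genes": sorted(
            g for g, s in etruth.profile_of_gene.items() if tuple(s) == DECREASING_SHAPE
        ),
        "planted_triplets": ["|".join(t) for t in ctruth.triplets],
        "cis_pairs": {f"{a}|{b}": d for (a, b), d in atruth.cis_pairs.items()},
        "non_cis_pairs": {f"{a}|{b}": d for (a, b), d in atruth.non_cis_pairs.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    print(f"wrote synthetic inputs to {out}/")
    print(f"  {matrix.n_genes} genes x {matrix.n_samples} samples; "
          f"{len(truth['planted_profile_genes'])} planted on {DECREASING_SHAPE}")
    print(f"  {len(ctruth.triplets)} planted ceRNA triplets; "
          f"{len(atruth.cis_pairs)} cis pairs; {len(aim)} LID animals scored")


if __name__ == "__main__":
    main()
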