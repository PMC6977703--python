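#!/usr/bin/env python
"""Build the co-expression and ceRNA networks and predict cis/trans targets.

The ceRNA construction keeps lncRNA x mRNA pairs at the 99th percentile
of the correlation pool and restricts them to triplets where both
members carry a perfect 6mer seed site of the shared miRNA; with planted
truth available the script verifies perfect recovery.  Cis targets are
genes within 10 kb of a lncRNA locus; trans targets come from the
k-mer screen plus ungapped antisense duplex score.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import cerna_profiler as cp


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    truth = json.loads((args.data / "truth.json").read_text())

    header = pd.read_csv(args.data / "cerna_expression.tsv", sep="\t", nrows=0)
    cmap = {s: s.rsplit("_r", 1)[0] for s in header.columns[1:]}
    cmatrix = cp.read_expression_matrix(
        args.data / "cerna_expression.tsv", cmap, ["Sham", "PD", "NLID", "LID"]
    )
    from cerna_profiler.core_io import read_fasta, read_mirnas

    lnc_seqs = read_fasta(args.data / "lncrnas.fa")
    mrna_seqs = read_fasta(args.data / "mrnas.fa")
    mirnas = read_mirnas(args.data / "mirnas.fa")
    sequences = {**lnc_seqs, **mrna_seqs}

    # co-expression network at r >= 0.99 over the ceRNA instance
    edges = cp.coexpression_network(cmatrix, r_threshold=0.99)
    cp.write_network(
        [(e.gene_a, e.gene_b, {"r": e.r}) for e in edges],
        args.out / "coexpression.tsv",
    )
    print(f"co-expression network: {len(edges)} edges at r >= 0.99")

    triplets = cp.build_cerna_network(
        cmatrix, sorted(lnc_seqs), sorted(mrna_seqs), mirnas, sequences, percentile=99.0
    )
    pd.DataFrame(
        [
            {"lncrna": t.lncrna_id, "mirna": t.mirna_id, "mrna": t.mrna_id,
             "r": t.r_pair, "n_sites_lnc": t.n_sites_lncrna, "n_sites_mrna": t.n_sites_mrna}
            for t in triplets
        ]
    ).to_csv(args.out / "cerna_triplets.tsv", sep="\t", index=False)
    got = {f"{t.lncrna_id}|{t.mirna_id}|{t.mrna_id}" for t in triplets}
    planted = set(truth["planted_triplets"])
    print(f"ceRNA network: {len(triplets)} triplets; "
          f"planted recovered {len(got & planted)}/{len(planted)}, "
          f"background {len(got - planted)}")

    records = cp.read_transcripts(args.data / "annotation.gtf")
    lncs = [r for r in records if r.transcript_id.startswith("lnc_")]
    genes = [r for r in records if r.transcript_id.startswith("gene_")]
    cis = cp.cis_targets(lncs, genes, window_bp=10_000)
    pd.DataFrame(
        [{"lncrna_id": h.lncrna_id, "gene_id": h.gene_id, "distance_bp": h.distance_bp}
         for h in cis]
    ).to_csv(args.out / "cis_targets.tsv", sep="\t", index=False)
    cis_got = {f"{h.lncrna_id}|{h.gene_id}" for h in cis}
    print(f"cis targets: {len(cis)} hits within 10 kb "
          f"(planted {len(cis_got & set(truth['cis_pairs']))}/{len(truth['cis_pairs'])}, "
          f"false {len(cis_got - set(truth['cis_pairs']))})")

    lnc0 = sorted(lnc_seqs)[0]
    trans = cp.trans_targets(
        lnc_seqs[lnc0], mrna_seqs, min_score=20, screen_kmer=12, lncrna_id=lnc0
    )
    pd.DataFrame(
        [{"lncrna_id": h.lncrna_id, "target_id": h.target_id, "best_score": h.best_score}
         for h in trans]
    ).to_csv(args.out / "trans_targets.tsv", sep="\t", index=False)
    print(f"trans targets of {lnc0}: {len(trans)} "
          "(none expected: backgrounds are screened clean)")


if __name__ == "__main__":
    main()
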