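"""Association screens: candidate co-expression and clinical variables.

Computes the Spearman correlation matrix over the candidate panel (pairs with
r >= 0.60 flagged co-expressed) and tests each candidate against age, sex,
malignancy, grade and stage; Dunn's pairwise comparisons follow any
significant Kruskal-Wallis stage result.
"""

import argparse
from pathlib import Path

from mirnorm import clinical_association, coexpression_screen, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    rq = io.read_matrix(args.results / "rq.tsv")
    meta = io.read_table(args.results / "simulated" / "sample_meta.tsv", index_col=0)

    co = coexpression_screen(rq)
    io.write_matrix(co.spearman_r, args.results / "spearman_r.tsv", kind="spearman")
    print(f"co-expressed pairs (r >= {co.threshold}): {len(co.coexpressed_pairs)}")
    for a, b, r in co.coexpressed_pairs[:10]:
        print(f"  {a} ~ {b}: r = {r:.2f}")

    cl = clinical_association(rq, meta)
    io.write_table(cl.clinical, args.results / "clinical.tsv", kind="clinical", index=False)
    hits = cl.clinical[cl.clinical["p_value"] < 0.05]
    print(f"clinical associations at p < 0.05: {len(hits)} of {len(cl.clinical)} tests")
    for _, row in hits.iterrows():
        print(f"  {row['gene']} ~ {row['variable']} ({row['test']}): p = {row['p_value']:.4f}")
    if cl.posthoc is not None:
        io.write_table(cl.posthoc, args.results / "dunn_posthoc.tsv",
                       kind="posthoc", index=False)


if __name__ == "__main__":
    main()
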