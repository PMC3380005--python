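"""Stability ranking of the candidate panel by geNorm, NormFinder, BestKeeper.

Produces per-method reports, the merged consensus table, the geNorm V-curve
(table and figure), and checks the rankings against the planted truth: the
deregulated assays should populate the worse half of every ranking.
"""

import argparse
from pathlib import Path

import yaml

from mirnorm import bestkeeper, consensus_table, genorm, io, normfinder
from mirnorm.plots import plot_v_curve


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    rq = io.read_matrix(args.results / "rq.tsv")
    cq_means = io.read_matrix(args.results / "cq_means.tsv")
    meta = io.read_table(args.results / "simulated" / "sample_meta.tsv", index_col=0)
    assays = io.read_table(args.results / "simulated" / "assays.tsv", index_col=0)
    truth = yaml.safe_load((args.results / "simulated" / "truth_qpcr.yaml").read_text())

    gn = genorm(rq)
    nf = normfinder(rq, groups=meta["group"])
    bk = bestkeeper(cq_means, efficiencies=assays["efficiency"])
    for rep in (gn, nf, bk):
        io.write_table(rep.table, args.results / f"{rep.method}.tsv", kind=rep.method)
    io.write_table(gn.extras["v_series"], args.results / "genorm_v_curve.tsv",
                   kind="v_curve", index=False)
    plot_v_curve(gn.extras["v_series"], gn.extras["v_cutoff"],
                 args.results / "genorm_v_curve.png")
    io.write_table(consensus_table([gn, nf, bk]), args.results / "consensus.tsv",
                   kind="consensus")

    print(f"geNorm: best single {gn.best_single}, best pair {gn.best_pair}, "
          f"recommended set {gn.recommended_set or 'none (all V >= cutoff)'}")
    print(f"NormFinder: best single {nf.best_single}, best pair {nf.best_pair}")
    print(f"BestKeeper: best single {bk.best_single}, "
          f"excluded (SD > 1 cycle): {bk.extras['excluded'] or 'none'}")

    dereg = {a for a in rq.index if a not in set(truth["stable_assays"])}
    k = rq.shape[0]
    for rep in (gn, nf, bk):
        ranks = rep.table["rank"].dropna()
        in_worse = sum(1 for a in dereg if a in ranks.index and ranks[a] > k / 2)
        print(f"  {rep.method}: {in_worse}/{len(dereg)} planted-deregulated assays "
              "in the worse half")


if __name__ == "__main__":
    main()
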