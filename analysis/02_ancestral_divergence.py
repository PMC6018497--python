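"""Ancestral LAS deduction and per-species Poisson-corrected divergence.

On the same simulated grouped alignment (with a 3x-rate focal lineage to
emulate the fast-evolving sea-cucumber LAS genes), deduces the ancestral
animal sequence by the two-of-three clade majority rule, measures each
animal sequence's Poisson-corrected distance from it with bootstrap
standard errors, and checks the deduced ancestor against the known root.
"""

import argparse
from pathlib import Path

from holotools.alignment_prep import filter_gap_columns, group_profile
from holotools.ancestral import CLADE_ORDER, deduce_ancestral, divergence_table
from holotools.synthetic import MsaScenario, simulate_osc_msa


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--out-dir", type=Path, default=Path("results/ancestral"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    scenario = MsaScenario(seed=args.seed, focal_rate_multiplier=3.0)
    aln, groups, truth = simulate_osc_msa(scenario)
    filtered, cmap = filter_gap_columns(aln)
    profiles = {c: group_profile(filtered, groups, animal_clade=c) for c in CLADE_ORDER}
    anc = deduce_ancestral(profiles)

    determined = correct = 0
    for fc, res in enumerate(anc.residues):
        if res != "X":
            determined += 1
            correct += res == truth.ancestral[cmap.to_original(fc)]
    table = divergence_table(filtered, groups, anc,
                             n_replicates=args.bootstrap, seed=args.seed)
    table.to_csv(args.out_dir / "divergence.tsv", sep="\t", index=False,
                 float_format="%.6g")
    (args.out_dir / "ancestral.fasta").write_text(
        ">ancestral_animal_LAS\n" + anc.residues + "\n")

    print(f"ancestral: {determined}/{len(anc.residues)} columns determined, "
          f"{correct}/{determined} match the true root")
    top = table.iloc[0]
    print(f"most divergent: {top['id']} (d = {top['d']:.3f} +/- {top['se']:.3f}); "
          f"focal lineage ranked first: {top['id'] == truth.focal_id}")
    print(f"table written to {args.out_dir}/divergence.tsv")


if __name__ == "__main__":
    main()
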