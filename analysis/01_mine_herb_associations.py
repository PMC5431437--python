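"""Rank candidate herbs by hypergeometric co-occurrence with the disease.

Document counts are inputs to this analysis (the corpus search itself is
manual); the counts used here are synthetic but shaped like a literature
search for erectile dysfunction: a large corpus, a small disease slice,
and herbs whose joint counts range from chance-level to strongly
enriched. The driver writes the ranked association table and reports
which herbs clear the P < 0.01 cutoff.
"""

import argparse
from pathlib import Path

from formulanet.herb_mining import CorpusCounts, rank_herbs

SYNTHETIC_COUNTS = [
    # herb, N, K, n, k  (synthetic corpus counts)
    ("Gymnadenia Conopsea", 2_000_000, 4_000, 150, 12),
    ("Stigma Croci", 2_000_000, 4_000, 2_600, 35),
    ("Semen Strychni", 2_000_000, 4_000, 1_900, 18),
    ("Boswellia", 2_000_000, 4_000, 3_100, 28),
    ("Myristica Semena", 2_000_000, 4_000, 1_200, 14),
    ("Syringa Oblata", 2_000_000, 4_000, 450, 7),
    ("Rhizoma Alpiniae Officinarum", 2_000_000, 4_000, 800, 10),
    ("Papaveris Pericarpium", 2_000_000, 4_000, 700, 2),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", default="results", type=Path)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    batch = [(h, CorpusCounts(N, K, n, k)) for h, N, K, n, k in SYNTHETIC_COUNTS]
    table = rank_herbs(batch)
    out = args.out_dir / "herb_associations.tsv"
    table.to_csv(out, sep="\t", index=False)

    n_sig = int(table["significant"].sum())
    print(f"{n_sig}/{len(table)} herbs significantly associated (P < 0.01)")
    for row in table.itertuples(index=False):
        flag = "*" if row.significant else " "
        print(f"  {flag} {row.herb:<30s} P = {row.p_value:.3g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
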