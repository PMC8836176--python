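"""Score the bundled reference sequences: the canonical sponge pair.

Computes, on the bundled LINC02802 / miR-486-5p / MAML3-3'UTR sequences:
the weighted-alignment score and hybridization energy of the
lncRNA:miRNA pair (wild type and binding-site mutant), and the canonical
seed-site architecture of the lncRNA and the 3'UTR. Writes
``results/printed_sequences.tsv`` and prints a short narrative.

Run from the repository root: ``python analysis/01_printed_sequences.py``
"""

from pathlib import Path

import pandas as pd

from spongescan import fixtures
from spongescan.duplex import hybrid_mfe, miranda_align
from spongescan.seeds import scan_seed_sites

OUT = Path("results")
OUT.mkdir(exist_ok=True)


def main() -> None:
    mir = fixtures.mir486_5p()
    rows = []
    for target in (fixtures.linc02802(), fixtures.linc02802_mut()):
        hits = miranda_align(mir, target)
        ehit = hybrid_mfe(mir, target)
        rows.append({
            "target": target.id,
            "length_nt": target.length,
            "best_align_score": hits[0].align_score if hits else None,
            "align_site": f"{hits[0].target_start}-{hits[0].target_end}" if hits else "none",
            "mfe_kcal_mol": ehit.mfe if ehit else None,
            "seed_sites": ";".join(
                f"{s.site_type}@{s.start}-{s.end}" for s in scan_seed_sites(mir, target)
            ) or "none",
        })
    maml3 = fixtures.maml3_3utr()
    rows.append({
        "target": maml3.id,
        "length_nt": maml3.length,
        "best_align_score": None,
        "align_site": "n/a (mRNA edge uses seed sites)",
        "mfe_kcal_mol": None,
        "seed_sites": ";".join(
            f"{s.site_type}@{s.start}-{s.end}" for s in scan_seed_sites(mir, maml3)
        ),
    })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "printed_sequences.tsv", sep="\t", index=False)

    wt, mut = df.iloc[0], df.iloc[1]
    print(df.to_string(index=False))
    print()
    print(f"miR-486-5p vs {wt.target}: score {wt.best_align_score} at {wt.align_site}, "
          f"mfe {wt.mfe_kcal_mol} kcal/mol; the single 7mer-m8 site sits at 161-167.")
    print(f"The binding-site mutant drops the score to "
          f"{mut.best_align_score if mut.best_align_score is not None else '<threshold'} "
          f"and raises the energy to {mut.mfe_kcal_mol} kcal/mol; its seed site is gone.")
    print(f"The 3'UTR presents {df.iloc[2].seed_sites} - one 8mer plus one 7mer site.")
    print("See docs/methods.md for how these computed values relate to the "
          "originally reported tool outputs.")


if __name__ == "__main__":
    main()
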