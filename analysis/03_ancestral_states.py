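"""Brownian-motion ancestral states for the trait tables, both branch-length
variants.

Maximum-likelihood ancestral estimates with 95% CIs are computed at the 12
internal nodes for every muscle and family, on the time-calibrated tree and
on the punctuated (all-branch-lengths-one) variant, and written in the
five-family ACE CSV dialect.
"""

from pathlib import Path

import pandas as pd

import archolimb as al
from archolimb.phylo import STUDY_NODES, punctuated_tree
from archolimb.tables import FAMILIES, write_ace_csvs

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    tree = al.study_tree()
    variants = {"time": tree, "punctuated": punctuated_tree(tree)}
    for tag, t in variants.items():
        payload = {}
        for family in FAMILIES:
            path = BASE / f"traits_{family}.csv"
            if not path.exists():
                continue
            traits = pd.read_csv(path, index_col=0)
            payload[family] = al.ace_all(
                t, traits, node_order=tuple(STUDY_NODES)
            )
        out = BASE / f"ace_{tag}"
        paths = write_ace_csvs(payload, out, tag=tag)
        print(f"{tag}: wrote {len(paths)} ACE tables to {out}")
        est = payload["knee_Ex"]["estimate"]
        print(
            f"  FMTE knee ACE: Archosauria {est.loc['FMTE', 'Archosauria']:.4f}"
            f" -> Phasianidae {est.loc['FMTE', 'Phasianidae']:.4f}"
        )


if __name__ == "__main__":
    main()
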