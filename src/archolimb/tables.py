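"""Trait tables and the ACE CSV dialect.

Trait tables are (MTU x taxon) matrices of mean normalized moment arms, one
per joint/DoF family.  Ancestral-state results travel as (MTU x node) CSV
matrices in five families named like the study's processed data files:

    hip_Ex_ACE_data_from_dino_moment_arms_<tag>.csv      (hip FLEXEX)
    hip_Ab_...  (hip ABAD),  hip_Ro_...  (hip LAR)
    knee_Ex_... (knee FLEXEX),  ankle_Ex_... (ankle FLEXEX)

Companion files with ``_CI_lower`` / ``_CI_upper`` before ``.csv`` carry the
confidence bounds.  The first column is the MTU acronym; remaining columns
are internal-node names.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

#: family key -> (joint, dof)
FAMILIES = {
    "hip_Ex": ("hip", "FLEXEX"),
    "hip_Ab": ("hip", "ABAD"),
    "hip_Ro": ("hip", "LAR"),
    "knee_Ex": ("knee", "FLEXEX"),
    "ankle_Ex": ("ankle", "FLEXEX"),
}
FAMILY_BY_JOINT_DOF = {v: k for k, v in FAMILIES.items()}

_FILE_RE = re.compile(
    r"^(?P<family>hip_Ex|hip_Ab|hip_Ro|knee_Ex|ankle_Ex)_ACE_data"
    r".*?(?P<kind>_CI_lower|_CI_upper)?\.csv$"
)


def build_trait_table(sweep_df: pd.DataFrame, joint: str, dof: str,
                      lost_policy: str = "zero",
                      itc_policy: str = "copy_ife") -> pd.DataFrame:
    """Assemble the (MTU x taxon) trait matrix for one joint/DoF family from
    the long-format sweep table.

    ``lost_policy``: "zero" encodes lost muscles as trait value 0 (the
    study's treatment); "missing" leaves NaN.  ``itc_policy``: "copy_ife"
    fills the ITC's value in taxa that predate its origin (crocodylians)
    with the undivided IF/IFE value of the same taxon, so the trait is
    defined back to the deepest node; "zero" leaves the lost encoding.
    """
    sub = sweep_df[(sweep_df["joint"] == joint) & (sweep_df["dof"] == dof)]
    table = sub.pivot_table(
        index="mtu", columns="taxon", values="mean_normalized", aggfunc="first"
    )
    if "lost" in sub.columns and lost_policy == "missing":
        lost = sub.pivot_table(
            index="mtu", columns="taxon", values="lost", aggfunc="first"
        ).astype(bool)
        table = table.mask(lost)
    if itc_policy == "copy_ife" and "ITC" in table.index and "IFE" in table.index:
        if "lost" in sub.columns:
            lost = sub.pivot_table(
                index="mtu", columns="taxon", values="lost", aggfunc="first"
            ).astype(bool)
            for taxon in table.columns:
                if lost.loc["ITC", taxon]:
                    table.loc["ITC", taxon] = table.loc["IFE", taxon]
    table.index.name = "MTU"
    table.columns.name = None
    return table


def family_filename(family: str, tag: str = "synthetic",
                    kind: str = "estimate") -> str:
    suffix = {"estimate": "", "ci95_low": "_CI_lower", "ci95_high": "_CI_upper"}[kind]
    return f"{family}_ACE_data_from_dino_moment_arms_{tag}{suffix}.csv"


def write_ace_csvs(ace_by_family: dict[str, dict[str, pd.DataFrame]],
                   out_dir: str | Path, tag: str = "synthetic") -> list[Path]:
    """Write estimate + CI tables for each family into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for family, tables in ace_by_family.items():
        if family not in FAMILIES:
            raise ValueError(f"unknown ACE family {family!r}")
        for kind in ("estimate", "ci95_low", "ci95_high"):
            if kind not in tables:
                continue
            path = out_dir / family_filename(family, tag, kind)
            tables[kind].to_csv(path, float_format="%.10g")
            written.append(path)
    return written


def read_ace_csv(path: str | Path) -> pd.DataFrame:
    """Read one (MTU x node) ACE matrix, validating the header."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "MTU":
        raise ValueError(
            f"{path.name}: not an ACE table (first column is "
            f"{df.columns[0]!r}, expected 'MTU')"
        )
    df = df.set_index("MTU")
    try:
        return df.astype(float)
    except ValueError as err:
        raise ValueError(f"{path.name}: non-numeric ACE cell ({err})")


def read_ace_dir(directory: str | Path,
                 kinds: tuple[str, ...] = ("estimate",)) -> dict[str, dict[str, pd.DataFrame]]:
    """Auto-detect and read the five-family ACE CSVs from a directory.

    Returns ``{family: {kind: table}}``; missing CI companions are simply
    absent.  Raises if no estimate file of any family is found.
    """
    directory = Path(directory)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for path in sorted(directory.glob("*.csv")):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        family = m.group("family")
        kind = {
            None: "estimate", "_CI_lower": "ci95_low", "_CI_upper": "ci95_high"
        }[m.group("kind")]
        if kind not in kinds and kind != "estimate":
            continue
        out.setdefault(family, {})[kind] = read_ace_csv(path)
    if not any("estimate" in v for v in out.values()):
        raise FileNotFoundError(
            f"no ACE estimate CSVs found under {directory}"
        )
    return out


def estimates_by_joint_dof(ace_by_family: dict[str, dict[str, pd.DataFrame]]
                           ) -> dict[str, pd.DataFrame]:
    """Re-key estimate tables as ``"{joint}_{dof}"`` for trend analysis."""
    out = {}
    for family, tables in ace_by_family.items():
        joint, dof = FAMILIES[family]
        out[f"{joint}_{dof}"] = tables["estimate"]
    return out
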