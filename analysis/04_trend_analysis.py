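"""Leverage-ratio trends: internodal changes, switches, extrema, recovery.

Reads the time-calibrated ACE tables, reports the programmed-trend recovery
(FMTE's overall change, programmed at -50%), the detected action switches
(GM is programmed to flip at Phasianidae), and per-muscle peak/minimum
nodes; writes tidy CSV reports.
"""

from pathlib import Path

from archolimb.tables import estimates_by_joint_dof, read_ace_dir
from archolimb.trends import detect_extrema, detect_switches, internodal_changes

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    ace = read_ace_dir(BASE / "ace_time")
    est = estimates_by_joint_dof(ace)
    out = BASE
    for key, table in est.items():
        switches = detect_switches(table)
        extrema = detect_extrema(table)
        switches.to_csv(out / f"switches_{key}.csv", index=False)
        extrema.to_csv(out / f"extrema_{key}.csv", index=False)
        if not switches.empty:
            print(f"{key}: switches at", switches.to_dict("records"))
    rep = internodal_changes(est["knee_FLEXEX"].loc["FMTE"].rename("FMTE"))
    rep.internodal.to_csv(out / "changes_FMTE_knee.csv", index=False)
    print(
        f"FMTE knee leverage overall change {rep.overall_pct:+.1f}% "
        "(programmed -50%); reliable steps:"
    )
    print(rep.reliable_steps().to_string(index=False))


if __name__ == "__main__":
    main()
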