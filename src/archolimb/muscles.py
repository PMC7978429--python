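"""Roster of the major archosaurian hindlimb muscle-tendon units (MTUs).

Acronyms follow the crocodylian nomenclature conventional in archosaur
myology (CFL = M. caudofemoralis longus, ILFB = M. iliofibularis, ...).
Each entry records which joints the MTU crosses (hence which moment arms it
has), the avian homolog where one exists, and phylogenetic presence rules:
a few muscles are lost on the bird-line (FTI1 and PIFE3 between stem birds
and crown birds) and the ITC is an innovation of Dinosauromorpha, absent in
crocodylians (where the undivided IF is its precursor).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MuscleInfo:
    acronym: str
    crocodylian_name: str
    avian_name: str | None
    joints: tuple[str, ...]  # joints the MTU crosses ("hip", "knee", "ankle")
    main_action: str
    lost_in: tuple[str, ...] = ()  # clades where the MTU is absent
    evolved_in: str | None = None  # clade of origin if not ancestral


# Clades used by presence rules.  "Phasianidae" stands in for crown birds;
# losses "between Avialae and Aves" are therefore applied at Phasianidae.
_R = [
    ("CFL", "M. caudofemoralis longus", "M. caudofemoralis pars caudalis",
     ("hip",), "hip extensor"),
    ("CFB", "M. caudofemoralis brevis", "M. caudofemoralis pars pelvica",
     ("hip",), "hip extensor"),
    ("ILFB", "M. iliofibularis", "M. iliofibularis",
     ("hip", "knee"), "hip extensor/knee flexor"),
    ("ADD1", "M. adductor femoris 1", "M. puboischiofemoralis medialis",
     ("hip",), "hip adductor/hip extensor"),
    ("ADD2", "M. adductor femoris 2", "M. puboischiofemoralis lateralis",
     ("hip",), "hip adductor/hip extensor"),
    ("FTI1", "M. flexor tibialis internus 1", None,
     ("hip", "knee"), "hip extensor/knee flexor", ("Phasianidae",)),
    ("FTI3", "M. flexor tibialis internus 3", "M. flexor cruris medialis",
     ("hip", "knee"), "hip extensor/knee flexor"),
    ("FTE", "M. flexor tibialis externus",
     "M. flexor cruris lateralis pars pelvica",
     ("hip", "knee"), "hip extensor/knee flexor"),
    ("ISTR", "M. ischiotrochantericus", "M. ischiofemoralis",
     ("hip",), "hip extensor/hip lateral rotator"),
    ("AMB", "M. ambiens 1", "M. ambiens",
     ("hip", "knee", "ankle"), "hip flexor/knee extensor"),
    ("IT1", "M. iliotibialis 1", "M. iliotibialis cranialis",
     ("hip", "knee"), "hip flexor/knee extensor"),
    ("IT2", "M. iliotibialis 2", "M. iliotibialis lateralis pars preacetabularis",
     ("hip", "knee"), "hip flexor/knee extensor"),
    ("IT3", "M. iliotibialis 3", "M. iliotibialis lateralis pars postacetabularis",
     ("hip", "knee"), "hip extensor/knee extensor"),
    ("PIFE1", "M. puboischiofemoralis externus 1", "M. obturatorius lateralis",
     ("hip",), "hip flexor/hip lateral rotator"),
    ("PIFE2", "M. puboischiofemoralis externus 2", "M. obturatorius medialis",
     ("hip",), "hip flexor/hip lateral rotator"),
    ("PIFE3", "M. puboischiofemoralis externus 3", None,
     ("hip",), "hip flexor/hip lateral rotator", ("Phasianidae",)),
    ("PIFI1", "M. puboischiofemoralis internus 1", "M. iliofemoralis internus",
     ("hip",), "hip flexor/hip medial rotator"),
    ("PIFI2", "M. puboischiofemoralis internus 2", "M. iliotrochantericus cranialis",
     ("hip",), "hip flexor/hip medial rotator"),
    ("IFE", "M. iliofemoralis", "M. iliofemoralis externus",
     ("hip",), "hip abductor"),
    ("ITC", None, "M. iliotrochantericus caudalis",
     ("hip",), "hip abductor/hip medial rotator", (), "Dinosauromorpha"),
    ("FMTE", "M. femorotibialis externus", "M. femorotibialis lateralis",
     ("knee",), "knee extensor"),
    ("FMTI", "M. femorotibialis internus", "M. femorotibialis medialis",
     ("knee",), "knee extensor"),
    ("GL", "M. gastrocnemius lateralis", "M. gastrocnemius pars lateralis",
     ("knee", "ankle"), "knee flexor/ankle plantarflexor"),
    ("GM", "M. gastrocnemius medialis", "M. gastrocnemius pars medialis",
     ("ankle",), "ankle plantarflexor"),
    ("EDL", "M. extensor digitorum longus", "M. tibialis cranialis caput femorale",
     ("knee", "ankle"), "ankle dorsiflexor/knee extensor"),
    ("EHL", "M. extensor hallucis longus", "M. extensor hallucis longus",
     ("ankle",), "ankle dorsiflexor"),
    ("TA", "M. tibialis anterior", "M. tibialis cranialis caput tibiale",
     ("knee", "ankle"), "ankle dorsiflexor"),
    ("FDL", "M. flexor digitorum longus", "M. flexor digitorum longus",
     ("knee", "ankle"), "ankle plantarflexor/knee flexor"),
    ("FHL", "M. flexor hallucis longus", "M. flexor hallucis longus",
     ("knee", "ankle"), "ankle plantarflexor/knee flexor"),
    ("FL", "M. fibularis longus", "M. fibularis longus",
     ("ankle",), "ankle plantarflexor"),
    ("FLT", "M. fibularis longus (distal tendon)", "M. fibularis longus tendon",
     ("ankle",), "ankle plantarflexor"),
    ("FB", "M. fibularis brevis", "M. fibularis brevis",
     ("ankle",), "ankle dorsiflexor"),
]

ROSTER: dict[str, MuscleInfo] = {
    row[0]: MuscleInfo(
        acronym=row[0],
        crocodylian_name=row[1],
        avian_name=row[2],
        joints=row[3],
        main_action=row[4],
        lost_in=row[5] if len(row) > 5 else (),
        evolved_in=row[6] if len(row) > 6 else None,
    )
    for row in _R
}

#: MTUs crossing each joint (20 hip, 15 knee, 11 ankle).
HIP_MTUS = tuple(m for m, i in ROSTER.items() if "hip" in i.joints)
KNEE_MTUS = tuple(m for m, i in ROSTER.items() if "knee" in i.joints)
ANKLE_MTUS = tuple(m for m, i in ROSTER.items() if "ankle" in i.joints)

#: Sub-head groups whose mean normalized moment arms are averaged into a
#: single trait (two-headed muscles in particular clades).
SUBHEAD_GROUPS = {
    "IT2": ("IT2a", "IT2b"),
    "PIFI2": ("PIFI2a", "PIFI2b"),
    "ITC": ("ITCa", "ITCb"),
}


def is_known(acronym: str) -> bool:
    base = acronym.rstrip("ab")
    return acronym in ROSTER or base in ROSTER


def present_in(acronym: str, clade_path: tuple[str, ...]) -> bool:
    """Whether an MTU is present in a taxon whose root-to-tip clade
    membership is ``clade_path`` (e.g. ("Archosauria", ..., "Phasianidae"))."""
    info = ROSTER[acronym]
    if any(c in clade_path for c in info.lost_in):
        return False
    if info.evolved_in is not None and info.evolved_in not in clade_path:
        return False
    return True
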