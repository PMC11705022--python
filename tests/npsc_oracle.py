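"""Hand-worked NPSC scoring oracle cases shared by the unit and
acceptance suites.  Each expected tuple was traced through the
transcribed point schedule by hand once and frozen."""

def _profile(kj=0.0, satfat=0.0, sugars=0.0, sodium=0.0, fvnl=0.0, protein=0.0, fibre=0.0):
    return {
        "energy_kj": kj, "satfat_g": satfat, "sugars_g": sugars,
        "sodium_mg": sodium, "fvnl_pct": fvnl, "protein_g": protein,
        "fibre_g": fibre,
    }


# Hand-worked oracle: each case traced step by step through the
# transcribed schedule (threshold walks recorded in comments where
# non-obvious).  Tuples: (profile, category, baseline, V, P, F, score, pass)
ORACLE_CASES = [
    (_profile(), "cat2", 0, 0, 0, 0, 0, True),
    (_profile(), "cat1", 0, 0, 0, 0, 0, True),
    # kJ 200 -> 0; sugars 10 > 9 -> 2
    (_profile(kj=200, sugars=10), "cat1", 2, 0, 0, 0, 2, False),
    (_profile(kj=100, sugars=4.9), "cat1", 0, 0, 0, 0, 0, True),
    # sugars 5.1 > 5 -> 1; cat1 pass needs < 1
    (_profile(sugars=5.1), "cat1", 1, 0, 0, 0, 1, False),
    # kJ 840 -> 2, satfat 2 -> 1, sodium 300 -> 3; P 3, F 2
    (_profile(kj=840, satfat=2, sugars=4, sodium=300, protein=6, fibre=2),
     "cat2", 6, 0, 3, 2, 1, True),
    # baseline 5+4+5+9 = 23 >= 13 and V 0 -> protein gated
    (_profile(kj=1700, satfat=5, sugars=27, sodium=900, fvnl=20, protein=10, fibre=5),
     "cat2", 23, 0, 0, 5, 18, False),
    # same but fvnl 70 -> V 5 waives the gate
    (_profile(kj=1700, satfat=5, sugars=27, sodium=900, fvnl=70, protein=10, fibre=5),
     "cat2", 23, 5, 5, 5, 8, False),
    # sugars 30 -> 6; fvnl 100 -> V 8; negative score
    (_profile(kj=300, sugars=30, fvnl=100), "cat2", 6, 8, 0, 0, -2, True),
    # butter: kJ 3000 -> 8, satfat 55 > 52 -> 25, sodium 800 -> 8
    (_profile(kj=3000, satfat=55, sugars=0.5, sodium=800, protein=0.5),
     "cat3", 41, 0, 0, 0, 41, False),
    # light margarine: 4 + 7 + 0 + 7 = 18 < 28
    (_profile(kj=1500, satfat=8, sodium=700, protein=0.3), "cat3", 18, 0, 0, 0, 18, True),
    # cheese: kJ 1675 (not >1675) -> 4, satfat 21.6 (not >21.6) -> 16,
    # sodium 1800 > 1740 -> 16; protein 25 -> 5 (cat3 exempt from gate)
    (_profile(kj=1675, satfat=21.6, sodium=1800, protein=25), "cat3", 36, 0, 5, 0, 31, False),
    # cat3 eligibility boundary: 8 + 11 + 8 = 27 passes (< 28)
    (_profile(kj=2700, satfat=12, sodium=730), "cat3", 27, 0, 0, 0, 27, True),
    # ... and 8 + 11 + 9 = 28 fails
    (_profile(kj=2700, satfat=12, sodium=820), "cat3", 28, 0, 0, 0, 28, False),
    # gate edge: baseline exactly 13 (2+3+3+5) gates protein
    (_profile(kj=840, satfat=4, sugars=14, sodium=460, protein=8, fibre=1),
     "cat2", 13, 0, 0, 1, 12, False),
    # one sodium step lower: baseline 12 < 13, protein 8 -> 4 counts
    (_profile(kj=840, satfat=4, sugars=14, sodium=450, protein=8, fibre=1),
     "cat2", 12, 0, 4, 1, 7, False),
    # fruit juice: sugars 9 -> 1, fvnl 100 -> V 8
    (_profile(kj=180, sugars=9, sodium=10, fvnl=100), "cat1", 1, 8, 0, 0, -7, True),
    # nuts: kJ 2600 -> 7, satfat 7 -> 6, sodium 300 -> 3; fvnl 90 -> 6,
    # protein 20 -> 5, fibre 8 -> 5
    (_profile(kj=2600, satfat=7, sugars=5, sodium=300, fvnl=90, protein=20, fibre=8),
     "cat2", 16, 6, 5, 5, 0, True),
    (_profile(sodium=90), "cat2", 0, 0, 0, 0, 0, True),
    (_profile(sodium=90.5), "cat2", 1, 0, 0, 0, 1, True),
    (_profile(fvnl=25), "cat2", 0, 0, 0, 0, 0, True),
    (_profile(fvnl=25.5), "cat2", 0, 1, 0, 0, -1, True),
    (_profile(fibre=0.9), "cat2", 0, 0, 0, 0, 0, True),
    (_profile(fibre=1.0), "cat2", 0, 0, 0, 1, -1, True),
]

def _record_for_category_split(calcium_per100):
    """Dairy record whose NPSC category hinges on the calcium cut-off."""
    from reformulate.records import ProductRecord

    return ProductRecord(
        product_code="CHEESE", retailer_id="R1", tra_category="D",
        container_size=400.0, serving_size=100.0, serving_unit="g",
        nutrients={"calcium_mg": calcium_per100}, fvnl_percent=0.0,
        year_label="Y",
    )
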