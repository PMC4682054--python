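"""Reference composition of the developing kitten faecal microbiome.

Published average relative abundances (percent of annotated reads) of the
34 most abundant genera and their five phyla at 18, 30 and 42 weeks of
age.  These values calibrate the synthetic cohort generator: the per-age
genus mean vectors of the simulator reproduce this table, with the
remaining mass (undisplayed genera within the five phyla, plus genera of
other phyla) spread over a simulated rare tail.

Only genera reaching >= 0.3 % average relative abundance at at least one
sampling age are listed; phylum values include all genera of the phylum,
displayed or not.
"""

from __future__ import annotations

import pandas as pd

AGES = (18, 30, 42)

# genus -> (phylum, mean % at week 18, week 30, week 42)
GENUS_TABLE: dict[str, tuple[str, float, float, float]] = {
    "Atopobium":        ("Actinobacteria", 0.3, 0.5, 0.3),
    "Bifidobacterium":  ("Actinobacteria", 19.7, 10.1, 5.6),
    "Coriobacterium":   ("Actinobacteria", 1.1, 2.4, 1.7),
    "Eggerthella":      ("Actinobacteria", 0.4, 0.7, 0.6),
    "Mycobacterium":    ("Actinobacteria", 0.2, 0.3, 0.3),
    "Olsenella":        ("Actinobacteria", 0.4, 0.7, 0.5),
    "Slackia":          ("Actinobacteria", 0.2, 0.4, 0.3),
    "Streptomyces":     ("Actinobacteria", 0.3, 0.5, 0.4),
    "Alistipes":        ("Bacteroidetes", 0.1, 0.5, 0.6),
    "Bacteroides":      ("Bacteroidetes", 5.5, 11.8, 15.5),
    "Odoribacter":      ("Bacteroidetes", 0.1, 0.3, 0.6),
    "Parabacteroides":  ("Bacteroidetes", 0.3, 0.8, 1.1),
    "Prevotella":       ("Bacteroidetes", 2.9, 9.3, 13.8),
    "Acidaminococcus":  ("Firmicutes", 0.3, 0.5, 0.5),
    "Bacillus":         ("Firmicutes", 0.5, 0.7, 0.7),
    "Butyrivibrio":     ("Firmicutes", 0.5, 0.8, 0.7),
    "Cellulosilyticum": ("Firmicutes", 0.2, 0.3, 0.3),
    "Clostridium":      ("Firmicutes", 4.4, 6.9, 6.0),
    "Enterococcus":     ("Firmicutes", 0.2, 0.5, 0.3),
    "Eubacterium":      ("Firmicutes", 4.3, 5.3, 4.3),
    "Lactobacillus":    ("Firmicutes", 34.5, 12.4, 3.7),
    "Megasphaera":      ("Firmicutes", 0.1, 0.2, 8.4),
    "Oscillibacter":    ("Firmicutes", 0.5, 0.8, 0.7),
    "Paenibacillus":    ("Firmicutes", 0.2, 0.4, 0.4),
    "Roseburia":        ("Firmicutes", 2.0, 2.6, 2.1),
    "Ruminococcus":     ("Firmicutes", 0.4, 0.5, 0.4),
    "Selenomonas":      ("Firmicutes", 0.3, 0.6, 0.6),
    "Streptococcus":    ("Firmicutes", 0.7, 0.9, 0.9),
    "Burkholderia":     ("Proteobacteria", 0.4, 0.6, 0.6),
    "Desulfovibrio":    ("Proteobacteria", 0.2, 0.5, 0.5),
    "Escherichia":      ("Proteobacteria", 1.0, 0.1, 0.5),
    "Pseudomonas":      ("Proteobacteria", 0.3, 0.4, 0.4),
    "Shewanella":       ("Proteobacteria", 0.2, 0.3, 0.3),
    "Treponema":        ("Spirochaetes", 0.3, 0.5, 0.5),
}

# phylum -> mean % at (18, 30, 42); includes genera beyond those displayed
PHYLUM_TABLE: dict[str, tuple[float, float, float]] = {
    "Actinobacteria": (23.5, 17.5, 11.8),
    "Bacteroidetes":  (10.2, 25.1, 34.7),
    "Firmicutes":     (52.8, 40.7, 36.1),
    "Proteobacteria": (9.3, 10.5, 11.4),
    "Spirochaetes":   (0.8, 1.1, 1.0),
}


def genus_means_percent() -> pd.DataFrame:
    """Displayed genus means (percent), genera in rows, ages in columns."""
    df = pd.DataFrame(
        {g: v[1:] for g, v in GENUS_TABLE.items()}, index=list(AGES)).T
    df.index.name = "genus"
    return df


def phylum_means_percent() -> pd.DataFrame:
    df = pd.DataFrame(PHYLUM_TABLE, index=list(AGES)).T
    df.index.name = "phylum"
    return df


def genus_to_phylum() -> dict[str, str]:
    return {g: v[0] for g, v in GENUS_TABLE.items()}
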