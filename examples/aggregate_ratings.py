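"""From raw per-rater intensity ratings to an analysis-ready panel.

Writes a small long-format rating table (two raters in a select-then-
rate task), reads it back through the concept lexicon, averages it with
unselected concepts counting as zero intensity, min-max scales each
concept within the dataset, and prints the resulting matrix.
"""

import tempfile
from pathlib import Path

from gppca import (
    ConceptLexicon,
    average_panel,
    read_long_table,
    scale_unit_interval,
)

lexicon = ConceptLexicon(
    keys=("joy", "fear", "sadness"),
    translations={"VE": {"joy": "Alegria", "fear": "Miedo",
                         "sadness": "Tristeza"}},
)

rows = [
    "stimulus_id,dataset,rater_id,concept,intensity",
    "img1,VE,r1,Alegria,80",        # r1 selected only joy for img1
    "img1,VE,r2,alegria ,60",       # labels are trimmed and case-folded
    "img1,VE,r2,Miedo,20",
    "img2,VE,r1,Tristeza,90",
    "img2,VE,r2,Tristeza,70",
    "img3,VE,r1,Miedo,50",
    "img3,VE,r2,Alegria,40",
]
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "ratings.csv"
    path.write_text("\n".join(rows) + "\n")
    records = read_long_table(path, lexicon)

panel = average_panel(records, lexicon, unrated_as_zero=True)
print("averaged intensities (rows: stimuli, cols:", panel.concepts, ")")
print(panel.values["VE"])
scaled = scale_unit_interval(panel)
print("scaled to [0, 1] per concept:")
print(scaled.values["VE"])
# img1's joy cell is (80 + 60) / 2 = 70; its fear cell averages rater
# r1's implicit 0 with r2's 20 -> 10. After scaling, each concept
# column spans [0, 1] across the three stimuli within this dataset.
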