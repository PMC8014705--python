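# qualiannot

Headless qualitative image and ROI annotation for scientific imaging, with
the downstream analyses the annotations feed: distribution charts and
classification ground truth.

Routine image evaluation — scoring mitotic stages in time-lapse stacks,
ticking phenotype checkboxes for screening wells, describing each embryo on
a multi-object image — produces *qualitative* data that deserves the same
standardized handling as quantitative measurements. `qualiannot` models
that workflow as a library: an annotation *session* with a fixed keyword or
feature vocabulary, one table row per annotation *event* (one row per
referenced ROI), ImageJ-compatible ROI interchange, optional pixel
measurements per event, and exports for visualization and supervised
classification. It is written for image-analysis practitioners who want
scriptable, testable annotation data structures rather than a GUI.

## The model

Three annotation modalities, mirroring the three natural GUI idioms:

* **single-class (buttons)** — exactly one category keyword per event.
  Output either a single `Category` column or one binary column per
  keyword: each row is then a probability vector with 1 for the assigned
  category and 0 elsewhere (1-hot encoding, the form classification
  trainers expect). Keyboard slots F1..F12 map to categories in button
  order: slot *i* ↦ keywordᵢ.
* **multi-class (checkboxes)** — an independent boolean per keyword; a row
  may assert several keywords (multi-label). One 0/1 (or True/False)
  column per keyword.
* **multi-class (dropdown)** — one choice per named feature, defined in a
  simple CSV (one feature per column, label in the header, choices below);
  one table column per feature.

Events can reference ROIs: a ROI-Manager-equivalent store keeps them in
insertion order, the qualitative values are written into each ROI's
property map (`qa.*` keys), and ROIs round-trip through the binary ImageJ
`.roi` format and `RoiSet.zip` archives. With *run Measure* enabled, each
event also reports pixel statistics (Mean, Min, Max, StdDev, Area,
centroid, bounding box, perimeter; population-σ convention) over the ROI —
or the whole image when no ROI is selected.

Downstream, a table column becomes a **pie** tally; successive columns
become a **sunburst**, each column one ring deeper, where every node's
count is the sum of its children. For classifier training, single-class
tables export to 1-hot matrices, seeded **stratified splits** (per-class
largest-remainder rounding) into train/validation/test, class-folder trees
with a manifest, and **confusion matrices** whose trace counts agreements.

A synthetic-fixture module generates all three use cases (embryo images
with known phenotype triplets, mitotic-stage stacks, well directories) with
seed-deterministic, separable classes, so every pipeline stage can be
exercised end to end with a known answer.

## Worked example

```python
import qualiannot as qa

config = qa.SessionConfig(
    qa.Modality.SINGLE,
    keywords=("interphase", "prophase", "metaphase", "anaphase"),
    single_encoding=qa.SingleEncoding.ONE_HOT,
)
session = qa.create_session(config)
qa.record_event(session, qa.ImageLocator(".", "cell_000.tif"),
                qa.shortcut_to_keyword(config, 3))   # F3 = third button
qa.write_csv(session.table, "annotations.csv")
print(open("annotations.csv").read())
```

prints

```
Index,Folder,Image,Comment,Roi,interphase,prophase,metaphase,anaphase
1,.,cell_000.tif,,,0,0,1,0
```

— one row for the single annotation event; the four binary category
columns encode `metaphase` as the 1-hot vector `0,0,1,0`, summing to 1 as
every row must. Continuing with the dropdown modality:

```python
from qualiannot.synthetic_fixtures import worked_example_specs, make_embryo_image
image, rois, truth = make_embryo_image(worked_example_specs(), seed=0)
root = qa.sunburst(qa.to_dataframe(truth), ["texture", "pigmentation", "shape"])
print(root.count, {c.label: c.count for c in root.children})
```

prints `3 {'smooth': 2, 'granular': 1}`: three embryos total, two with
smooth and one with granular texture on the outer sunburst ring.

A `qualiannot` console command exposes the same operations
(`annotate`, `convert`, `measure`, `pie`, `sunburst`, `split`, `rois`,
`fixtures`); `qualiannot annotate` is a scripted terminal loop that keeps
the event semantics (one row per event, ordered shortcuts, auto-advance)
without a GUI.

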