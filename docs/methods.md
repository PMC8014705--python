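# Methods

## The annotation model

An annotation session is defined entirely by its `SessionConfig`: the
modality (single-class, multi-label checkboxes, or per-feature dropdowns),
the ordered vocabulary (keywords, or features with per-feature choice
lists), the single-class output encoding (category column vs 1-hot), the
browsing mode (stack, directory, none) and the measurement options. The
vocabulary is trimmed of surrounding whitespace and must be duplicate-free;
order is significant because it fixes both the table column order and the
keyboard-shortcut mapping (slot *i* ↦ the *i*-th keyword, slots 1..12).

One annotation *event* appends one table row per referenced ROI, or exactly
one row with no ROI reference when the event applies to the whole image.
This makes the table a flat event log: rows are insertion-ordered, deletion
preserves the order of the remainder, and a row never aggregates several
ROIs. Multi-label rows always carry the *complete* keyword set as boolean
flags — when a keyword is added mid-session, prior rows are rewritten with
the new flag false, so the schema is uniform regardless of when keywords
appeared. For one-hot output nothing needs rewriting: the binary columns
are derived from the stored category at serialization time.

Tables carry a fingerprint (truncated SHA-256 over the schema-determining
config parts: modality, ordered labels and choices, encoding) and refuse
records that do not validate against their config, so rows from mismatched
sessions cannot be mixed silently.

Browsing is modelled as a pure function: in directory mode the listing is
sorted lexicographically (case-sensitive, byte order) once at session
creation, and `advance` steps through it; in stack mode it increments the
configured axis of a named-axis, 1-based slice index (the ImageJ slice
convention). Exhaustion returns an explicit at-end sentinel — never a
wrap-around — which makes "repeated advance visits every item exactly
once" a testable invariant. Annotations on stacks record the filename plus
a slice column for the advance axis; whole-stack annotations simply leave
the slice cell empty.

## Table serialization

Column layout: `Index,Folder,Image,[slice axes],Comment,Roi`, then the
qualitative columns, then the measurement columns. The header is a pure
function of the config, so identical configs and records produce
byte-identical files. The `Index` column is 1-based and regenerated on
write (it is presentation, not identity). Files are UTF-8, RFC-4180 CSV
with CRLF row endings; comments may contain commas, quotes and newlines.
Boolean cells default to `0/1`, with a `True/False` dialect available;
reading accepts both dialects transparently, so either file can be
re-ingested or converted. Measurements are written with `repr(float)`
(shortest round-tripping representation), which makes write→read an exact
identity. One-hot rows are validated on read: a row whose category cells do
not sum to exactly one is rejected with its row number.

The dropdown configuration CSV is parsed with features as columns: header
cell = feature label, cells below = choices, ragged column ends ignored.
The orientation is this package's convention and is symmetric to the
layout a user would naturally type in a spreadsheet; duplicate labels and
empty files are errors.

Known limitation: ROI names containing the `;` list separator would be
ambiguous in the `Roi` cell; the ROI store's generated names never contain
it.

## ImageJ ROI interchange

The `.roi` codec implements the public ImageJ binary layout: `Iout` magic,
big-endian 64-byte header (type code, bounds as 16-bit integers), vertex
arrays as 16-bit offsets from the bounding box, and a 64-byte header-2
block pointing at UTF-16BE name and properties strings. Supported kinds
and type codes: polygon 0, rectangle 1, oval 2, line 3, freehand 7,
point 10; composite/shape ROIs, splines and sub-pixel variants are out of
scope, and an unsupported type code raises rather than being skipped.
Properties are serialized as newline-separated `key=value` pairs, with
annotation-derived keys namespaced `qa.` so re-annotation can replace them
as a group while preserving unrelated properties (the operation is
idempotent per record). Consequently keys must not contain `=` and values
must not contain newlines. Coordinates are 0-based, origin top-left.
Interoperability is verified by encode→decode round-trips plus a frozen
layout test; pixel-identical agreement with a live ImageJ instance is not
claimed.

## Measurements

Rasterization decides which pixel centers `(x+0.5, y+0.5)` belong to a
ROI: rectangles cover `[left, left+w) × [top, top+h)`; ovals use the
inscribed ellipse with a strict interior test; polygons and freehand
outlines use the even-odd (crossing-number) rule. Masks are clipped to the
image and an empty intersection is an error. The even-odd-at-centers rule
is this package's convention; it can differ from ImageJ by ±1 boundary
pixel, which is documented and excluded from interoperability claims.

Statistics are computed over the masked intensities: Mean/Min/Max, StdDev
with the population (÷N) convention, Area as the pixel count at a
calibration of 1 pixel² (no spatial calibration metadata), centroid as the
mean of included pixel centers. Because the bounding box and the outline
perimeter are properties of the geometry, not the raster, the mask carries
the outline perimeter computed at rasterization time (exact polygon edge
length; Ramanujan's approximation for ellipses), and `measure` returns a
flat map keyed by table column names (`Mean, Min, Max, StdDev, Area, X, Y,
BX, BY, Width, Height, Perim`) so the four bounding-box numbers expand
naturally. The default measurement set is {Mean, Min, Max}; 32-bit float
images are handled natively.

## Distribution summaries

Pie and sunburst tallies operate on plain DataFrames (the CSV view of a
table), so they work on any table with the right columns. Labels are
ordered by first appearance — deterministic and faithful to annotation
order — with an opt-in sort by descending count; empty cells are tallied
under the reserved `(empty)` label. The sunburst is built recursively:
each node partitions its parent's rows by the next column, so
parent = Σ children holds at every depth and the one-column sunburst
coincides with the pie tally. For multi-label tables a convenience tally
counts "keyword asserted" across the boolean columns; one row may
contribute to several counts, so this is explicitly not a partition.
Rendering (matplotlib) is not contractual beyond slice fractions equalling
count/total; a sunburst written to an `.html` path is wrapped as a
standalone SVG page.

## Ground-truth exports

1-hot export applies to single-class tables (dropdown tables one feature at
a time); column order is vocabulary order and `argmax` inverts the
encoding. Record identity for splitting is the (folder, image, slice, ROI)
tuple, so ROI-level and per-slice classes split correctly; duplicate
identities are an error rather than a silent double-assignment.

The stratified split shuffles each class with a generator seeded once for
the whole split and apportions counts per class by largest-remainder
rounding, so each per-class count deviates from the exact fractional
product by less than one. Exact remainder ties (e.g. a half split of an
even class) are broken toward the split with the largest running global
deficit, then by declared order (train, val, test); this keeps the overall
counts matching the fractions too, instead of letting every class round
the same way. Default fractions are 0.7/0.15/0.15, a conventional choice
for small annotated image sets. The class-folder export writes the
`split/class/image` tree consumed by off-the-shelf classification
trainers, with a manifest CSV; missing images are reported, not fatal.
Model training itself is out of scope — the package prepares and evaluates
(confusion matrix, accuracy = trace/total), it does not train.

## Synthetic fixtures

The generators emulate the three study designs, not their optics. Embryo
images: elliptical objects on a dim background (mean 20, σ 2), with
pigmentation encoded as mean intensity (dark 60 vs clear 180), texture as
noise structure (smooth: additive σ 2; granular: multiplicative, CV 0.12)
and shape as the axis ratio (1.0 vs 1.8). With these numbers the dark/clear
gap (120) exceeds three pooled standard deviations even for clear granular
objects (σ ≈ 21.6), and an axis-ratio threshold of 1.3 separates the
shapes with zero error — so a trivial threshold classifier on the
measurements module must produce a diagonal confusion matrix, giving the
end-to-end tests a known answer. Mitosis stacks encode the stage in blob
geometry (round, speckled, elongated, split). Well directories encode
cystic morphology as dark holes in a bright organ blob, out-of-focus as a
Gaussian blur and empty as background only, with zero-padded filenames so
the lexicographic listing matches the truth-table order.

What the fixtures do **not** emulate: real point-spread functions, shading,
autofluorescence, class imbalance subtleties, annotator disagreement, or
hard boundary cases. Passing the end-to-end benchmark therefore shows the
pipeline plumbing is correct — events, ROIs, measurements, confusion —
not that any real classification task is easy.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small,
seed-deterministic problem sizes chosen as comfortable for a laptop-class
run while still exercising every code path: 25-row one-hot tables, 100
randomized ROIs per kind for round-trips, 50 random image+polygon pairs
(32×32) against the per-pixel brute-force oracle at 1e-9 relative
tolerance, 1,000-row tables for the conservation laws, and 24 embryos for
the classification benchmark. All randomness flows from a single seed
argument; generator outputs are bit-identical under a fixed seed. Strict
inequalities are used for interior tests (ellipse, even-odd crossings) so
half-integer pixel centers never sit exactly on integer-vertex boundaries.
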