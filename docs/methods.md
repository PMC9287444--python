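# Methods

## The iFDO model

An iFDO (image FAIR Digital Object) file describes one image *set* — a
deployment, dive or transect — in a single YAML document with two parts.
The `image-set-header` carries three set-level identity fields
(`image-set-name`, `image-set-uuid`, `image-set-handle`) plus default
values for any item-level field; `image-set-items` maps each image name
to the fields that deviate from those defaults. Resolution is an overlay
algebra: later layers win field by field, overlaying an empty layer is
the identity, and the three set-level fields never propagate into an
item. Videos are item records in list form — entry 0 holds video-wide
defaults, entries 1..n per-timepoint overrides — so a timepoint resolves
as header ⊕ entry 0 ⊕ entry *n*.

Item fields fall into three tiers. The *core* tier (identity, position,
time, ownership, licensing) is required: a document is FAIR-ready only
when every resolved item carries all of it. The *capture* tier
(acquisition technique, geometry, optics) is recommended; the *content*
tier (image-derived descriptors and annotations) optional. Validation
maps the tiers to severities — error / warning / info — and is pure:
the same document and vocabulary always yield the identical, ordered
report. Four capture fields are restricted to controlled values
(`image-acquisition`: photo, video, slide; `image-illumination`:
sunlight, artificial light, mixed light; `image-capture-mode`: timer,
manual, mixed; `image-deployment`: mapping, stationary, survey, …).
The deployment list is open-ended by design, so an unknown deployment
value warns instead of erroring.

Design choices where the standard leaves room:

- **Field spelling.** Files use the hyphenated `image-…` keys; in memory
  the prefix is stripped and hyphens become underscores. Fields outside
  the vocabulary round-trip verbatim and are reported at info severity —
  extensibility is a feature, not a fault.
- **Timestamps** are ISO 8601 strings with an explicit `Z`
  (`YYYY-MM-DDTHH:MM:SS.sssZ`). The YAML loader deliberately keeps
  timestamps as strings: converting them to datetime objects would
  destroy the lexical form (and the UTC designator) that validation
  checks and round-tripping preserves.
- **Depth** is meters below the sea surface, positive down; altitude
  above the seabed is the separate `image-meters-above-ground`.
- **Default CRS** is `EPSG:4326` when none is given.
- **Photo list form.** A photo written as a one-element list parses to
  the single-object form; the list form is reserved for videos.

## Identity and integrity

Each image and the set itself get a random version-4 UUID (122 free
bits, ≈5.3 × 10³⁶ values). The item UUID is *minted* into the image
file's metadata header: for JPEG the EXIF `ImageUniqueID` tag
(hyphen-stripped 32-hex, per EXIF ASCII convention), written by
splicing an APP1 segment into the byte stream so the compressed pixel
data is never touched; for PNG a `tEXt` chunk keyed `image-uuid`
inserted after `IHDR` by chunk-level byte surgery. Other formats fall
back to a `<file>.uuid` sidecar, allowed only explicitly and with a
warning. Identity is immutable: re-minting the same UUID is a byte-level
no-op, a different UUID is refused.

The SHA-256 file hash is computed **after** minting, streamed in 1 MiB
chunks, so the digest covers the identifier and verification can check
both at once. Handle URLs have the form
`<server>/<prefix>/<uuid>`, with the `@ifdo` suffix selecting the
metadata view and the bare form the data view; rendering and parsing are
inverses. The set UUID lives only in the iFDO file and is not minted
anywhere.

## Navigation curation

Raw underwater navigation mixes meter-scale jitter with spikes of tens
to hundreds of meters (acoustic dropouts, multipath). Curation is:

1. **Outlier rejection.** Positions are projected to a local
   equirectangular meter frame about the track's mean latitude
   (adequate at survey scales; degrades near the poles — a documented
   limitation). Each sample's horizontal distance to the centered
   running median (window 11 samples) is compared with the MAD of those
   distances within the window; samples beyond k = 5 MADs are removed,
   never replaced. Depth is screened the same way independently. The
   MAD is floored at 1 cm so static (moored) tracks divide cleanly.
   On a noise-free track this removes exactly the spikes. On a track
   with dense Gaussian noise the distance statistic is Rayleigh-like
   and its MAD is small relative to its tail, so the criterion also
   trims a fraction of ordinary noise samples — acceptable for imaging
   work, where the subsequent interpolation bridges removed samples,
   and the safety rail refuses to delete more than half a track.
2. **Smoothing.** Centered moving average (window 11), with shrinking
   symmetric windows near the ends so endpoints pass through. A
   constant-velocity track is a fixed point; white noise shrinks by
   about √window. Run after outlier removal — a mean is not
   spike-robust.
3. **Interpolation.** Image timestamps are geolocated by per-coordinate
   piecewise-linear interpolation (longitudes unwrapped across the
   antimeridian first); queries at sample times are exact. Queries
   beyond the track span are clamped within a 5 s tolerance and
   refused, per timestamp, beyond it. The reported
   `image-coordinate-uncertainty-meters` is the configured sensor
   uncertainty plus half the horizontal displacement of the bracketing
   pair: the position is known no better than the platform moves
   between fixes. This derivation is this package's choice; the
   standard names the field but not the estimator.

On the default synthetic conditions (see below) curation reduces the RMS
horizontal error from ≈9.1 m to ≈0.5 m and removes all injected spikes.

## Content descriptors and annotations

Grayscale conversion uses BT.601 luma (0.299 R + 0.587 G + 0.114 B,
rounded half-up). `image-entropy` is the Shannon entropy of the 256-bin
histogram (0 bits for a constant image, 8 for a uniform histogram) and
is invariant under pixel permutation. `image-average-colour` is the
per-channel mean to two decimals. `image-particle-count` binarizes
(Otsu by default, or a fixed level; bright-foreground by the dark-field
convention, invertible), labels 8-connected components and drops those
under `min_area` pixels. `image-mpeg7-colorstructure` is carried and
shape-validated (length 32/64/128/256) but never computed here.

Annotations are label(s) + annotator(s) + optional confidence attached
to pixel coordinates (0-based, origin top-left). Geometry follows from
the coordinate list: empty → whole image; one point → point; two points
with a declared bounding-box kind → axis-aligned box; ≥3 points with
the first repeated last → closed polygon. Confidence is per-annotation,
not per-label. Encoding and decoding are exact inverses and enforce
referential integrity against the label/creator tables.

## The factory

`create_ifdo` chains the steps a data curator performs after a cruise:
verify image times are UTC → curate the track → draw one set UUID and
per-image UUIDs (seedable, drawn in capture-time order so the result is
independent of directory listing order) → mint → rename to
`<project>_<event>_<sensor>_<YYYYMMDD>_<HHMMSS.sss>` (collisions get
`_1`, `_2`, …) → hash the minted files → interpolate positions →
derive the footprint where camera geometry and altitude are known
(nadir pinhole: width = 2 h tan(hfov/2); oblique viewports and housing
refraction are out of scope) → assemble the document with every
set-constant field factored into the header → validate. Error-severity
findings block emission unless forced, because FAIRness requires the
complete core. Image capture times come from embedded EXIF when
present, else the filename; a disagreement is an error, never a silent
preference. Minting and renaming happen in place, as they would on a
real data volume; the document itself is only produced whole.

## Synthetic data

The generator emulates a deep-sea towed-camera photo transect: a 600 s
track at 1 Hz moving ≈0.65 m/s with gentle sinusoidal cross-track
curvature over an abyssal site (≈11.85° N, 117.45° W, ≈4150 m), 0.5 m
Gaussian position noise, and five 100 m spikes at recorded indices —
magnitudes typical of acoustic-positioning dropouts. Images are
dark-field particle scenes: non-overlapping bright disks (radius 5 px,
value 200) on a uniform background (value 30), placed by rejection
sampling, written as lossless PNG so the recorded ground truth (count,
exact mean colour, histogram entropy) is bit-exact. The reference
dataset is 20 images across the track span with a complete project
configuration.

Everything is a pure function of its seed: the same call reproduces the
same bytes, and the manifest is the single oracle for recovery tests.
What the generator does **not** emulate — seafloor texture, lighting
falloff, correlated (random-walk) navigation drift, JPEG compression
noise — bounds what passing tests show: they demonstrate the pipeline's
contracts and recovery behaviour under the stated noise model, not
detector performance on real imagery.

## Numerical notes and limitations

- Serialization is canonical (set fields, version, defaults
  alphabetical, items alphabetical) and byte-stable; round-trip identity
  is asserted over randomized documents.
- Float comparisons in tests use absolute tolerances stated inline
  (1e-12 for interpolation against the brute-force oracle, 1e-9 for
  entropy closed forms).
- The equirectangular frame and linear (not great-circle) interpolation
  assume meter-scale sample spacing; both are documented approximations,
  fine for survey work, wrong for basin-scale tracks.
- ORCID validation checks the ISO 7064 mod 11-2 checksum, but the ORCID
  remains a bare identifier, not a resolvable URL — machine-actionable
  references are deferred by the standard itself, and the FAIR report's
  notes record the matching bookkeeping subtlety (two matrix rows are
  marked "in preparation" while the headline arithmetic
  41 − 2 − 3 = 36 counts the version-deferred rows separately).
- No video-container minting (MOV/MP4 atoms), no handle registration,
  no repository upload: those live in the surrounding infrastructure,
  not in this package.
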