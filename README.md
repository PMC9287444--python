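# ifdo — image FAIR Digital Objects for marine imagery

Marine imaging produces petabytes of photos and videos from AUVs, ROVs,
towed cameras and moorings, with wildly heterogeneous metadata. This
package implements the **iFDO** (image FAIR Digital Object) standard:
one YAML file per image set that makes the data Findable, Accessible,
Interoperable and Reusable by pairing every image — and the set — with
a persistent identifier (a random UUID4 inside a handle URL), a SHA-256
integrity hash, curated position data, and a controlled vocabulary of
acquisition and content metadata.

It is both a library and a command-line tool for the full life cycle:

- **model** — parse/serialize iFDO YAML with verbatim round-trip of
  extension fields; header-default / item-override resolution
  (`resolve_item`, `resolve_timepoint` for videos).
- **identity** — seedable UUID4 generation, minting UUIDs into JPEG
  (EXIF `ImageUniqueID`) and PNG (`tEXt` chunk) without touching pixel
  data, streamed SHA-256 with the mint-before-hash ordering, handle-URL
  construction (`…/<prefix>/<uuid>@ifdo` for metadata, bare for data),
  and file verification.
- **vocabulary** — tiered validation (required core → error,
  recommended capture → warning, unknown → info; restricted values
  checked against the shipped vocabulary) and the RDA FAIR-maturity
  report (41 recommendations: 36 achieved, 2 not applicable to images,
  3 deferred to a future standard version).
- **navigation** — track loading with UTC enforcement, running-median/
  MAD spike rejection, moving-average smoothing, and per-image
  geolocation by linear interpolation with a principled uncertainty.
- **content** — histogram entropy, average colour, particle counting
  (Otsu + connected components), and the point / bounding-box /
  polygon / whole-image annotation interchange encoding.
- **factory** — the end-to-end pipeline (`create_ifdo`) plus canonical
  renaming, camera footprints and footprint overlap.
- **fixtures** — deterministic synthetic datasets (particle images +
  noisy navigation tracks) with recorded ground truth.

## Worked example

Generate a synthetic 20-image towed-camera dataset, run the factory,
and inspect the result:

```sh
ifdo fixtures --seed 7 --out demo --images 20
ifdo create --images demo/images --nav demo/track.csv \
            --config demo/config.yaml --out demo/set.ifdo.yaml --seed 7
```

stderr ends with `wrote demo/set.ifdo.yaml with 20 items` and the exit
code is 1: warnings only (not every recommended capture field is
populated), no errors. The document begins:

```yaml
image-set-header:
  image-set-name: SO268 SO268-1_021 CAM-1
  image-set-uuid: 6513270e-269e-4d37-b2a7-4de452e6b438
  image-set-handle: https://hdl.handle.net/20.500.12085/6513270e-269e-4d37-b2a7-4de452e6b438@ifdo
  image-set-ifdo-version: 1.0.0
  ...
  image-license: CC-BY-4.0
  image-sensor: CAM-1
image-set-items:
  SO268_SO268-1_021_CAM-1_20220715_100030.000.png:
    image-coordinate-uncertainty-meters: 0.535
    image-datetime: '2022-07-15T10:00:30.000Z'
    image-depth: 4150.526995454546
    ...
```

Every value the whole set shares (license, sensor, camera footprint,
…) appears once in the header; each item carries only its own
timestamp, position, uncertainty, UUID and hash. The file has been
renamed to the canonical
`<project>_<event>_<sensor>_<date>_<time>` form, its UUID minted into
the PNG, and the hash computed on the minted bytes — so

```sh
ifdo verify demo/images/*.png --ifdo demo/set.ifdo.yaml   # every file: "verified"
ifdo validate demo/set.ifdo.yaml                          # "FAIR-ready: True"
ifdo report demo/set.ifdo.yaml
```

the last of which prints

```
RDA recommendations: 41 total, 36 achieved, 2 not applicable to images, 3 deferred to a future standard version
```

followed by the per-document checks (identifier valid, license present,
ORCID reference present, …).

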