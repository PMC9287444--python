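# Controlled iFDO vocabulary, version 1.0.0.
# Tiers: required (core) / recommended (capture) / optional (content).
version: "1.0.0"
required:
  - image-datetime
  - image-latitude
  - image-longitude
  - image-depth
  - image-coordinate-reference-system
  - image-coordinate-uncertainty-meters
  - image-uuid
  - image-hash-sha256
  - image-context
  - image-project
  - image-event
  - image-platform
  - image-sensor
  - image-abstract
  - image-pi
  - image-creators
  - image-license
  - image-copyright
recommended:
  - image-acquisition
  - image-deployment
  - image-illumination
  - image-capture-mode
  - image-area-square-meter
  - image-meters-above-ground
  - image-overlap-fraction
  - image-camera-housing-viewport
  - image-camera-calibration-model
  - image-objective
  - image-target-environment
  - image-fauna-attraction
  - image-temporal-constraints
optional:
  - image-entropy
  - image-particle-count
  - image-average-colour
  - image-mpeg7-colorstructure
  - image-annotation-labels
  - image-annotation-creators
  - image-annotations
restricted-values:
  image-acquisition: [photo, video, slide]
  image-deployment: [mapping, stationary, survey]
  image-illumination: [sunlight, artificial light, mixed light]
  image-capture-mode: [timer, manual, mixed]
# Fields whose value set may legitimately grow; out-of-set values are
# flagged as warnings rather than errors.
open-ended:
  - image-deployment
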