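"""Run-wide configuration and frozen constants.

All pipeline constants live here so that a run is fully described by one
:class:`RunConfig`, which can be serialized to (and reloaded from) a flat
``key = value`` text file. Reloading a snapshot reproduces the run bit for
bit given the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

#: Icosphere subdivision level of the ray template.
TEMPLATE_SUBDIVISION = 4

#: Fixed tilt (degrees, applied about x then y) that breaks the latitude
#: degeneracy of the symmetric icosphere so a latitude cut can retain
#: exactly 1016 directions.  Chosen once; never change silently.
TEMPLATE_TILT_DEG = (7.0, 3.0)

#: Latitude cut (degrees): directions with z >= sin(cut) are retained.
#: With the subdivision and tilt above this yields exactly 1016 directions,
#: with a z-gap of ~1.6e-4 to the first discarded vertex.
TEMPLATE_CUT_LATITUDE_DEG = 12.009184815018829

#: Number of template ray directions (vertices of the standardized surface).
N_TEMPLATE_VERTICES = 1016

#: Fixed one-hot order of the craniosynostosis class indicators.
SUBTYPE_ORDER = ("control", "plagiocephaly", "trigonocephaly", "scaphocephaly")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the defaults used throughout.

    Geometry, shape-model and network constants mirror the processing
    pipeline: a 1016-direction hemi-icosphere raycast representation, PCA
    to 32 components of which the 10 highest-variance scores feed the
    network together with 4 class indicators, and a small residual dense
    network trained with Adam at batch size 1.
    """

    # ray template
    template_subdivision: int = TEMPLATE_SUBDIVISION
    template_cut_latitude_deg: float = TEMPLATE_CUT_LATITUDE_DEG
    template_tilt_x_deg: float = TEMPLATE_TILT_DEG[0]
    template_tilt_y_deg: float = TEMPLATE_TILT_DEG[1]

    # shape model
    n_components: int = 32
    n_features: int = 10

    # network architecture
    input_dim: int = 14
    hidden_width: int = 8
    n_identity_blocks: int = 3
    dropout_in: float = 0.5
    dropout_out: float = 0.1
    output_dim: int = 3

    # training schedule
    lr0: float = 1e-3
    decay_factor: float = 0.5
    decay_every: int = 100
    batch_size: int = 1
    epochs: int = 400
    folds: int = 5

    # statistics
    alpha: float = 0.05

    # reproducibility
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        """Write the config as flat ``key = value`` lines."""
        lines = [
            f"{f.name} = {getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Reload a config snapshot written by :meth:`to_file`."""
        import ast

        kwargs = {}
        names = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in names:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
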