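"""Tiny model/dataset builders shared across test modules."""

from __future__ import annotations

from msa3d import MSA3D, FusionConfig, PhantomSpec, generate_dataset
from msa3d.mvssn import SliceNetConfig
from msa3d.s3dcnn import SubjectNetConfig

TINY = (12, 14, 12)
TINY_SUBJECT = SubjectNetConfig(blocks=(
    (3, 1, 1, 8, 3, 2), (3, 1, 1, 16, 3, 2), (3, 1, 1, 32, 3, 2)))


def tiny_model(seed: int = 0, use_sam: bool = True) -> MSA3D:
    return MSA3D(TINY, slice_cfg=SliceNetConfig(weight_sharing="per_view"),
                 subject_cfg=TINY_SUBJECT,
                 fusion_cfg=FusionConfig(hidden=32, use_sam=use_sam), seed=seed)


def tiny_dataset(n_per_class: int = 6, seed: int = 0, effect: float = 0.8):
    spec = PhantomSpec(shape=TINY, lesion_radii=(2, 2, 2), effect_size=effect,
                       noise_sd=0.05)
    return generate_dataset(n_per_class, spec, jitter=(1, 1, 1), seed=seed)
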