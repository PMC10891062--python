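"""Iterative pseudo-balancing for colony microscopy image classification.

A student-teacher meta-pseudo-label training framework that rebalances an
imbalanced, largely unlabeled image collection on the fly by resampling
pseudo-labeled patches with class weights inversely proportional to the
teacher's estimated class proportions.  Ships with the full surrounding
stack: a seeded synthetic-microscopy fixture generator, the morphological
colony-segmentation pipeline, multi-scale in-mask patch sampling, compact
NumPy classifier networks, the training loop, and evaluation/reporting.
"""

from importlib import import_module

__all__ = [
    "config",
    "evaluation",
    "models",
    "nn",
    "patches",
    "segmentation",
    "synth",
    "training",
]

__version__ = "0.1.0"


def __getattr__(name):
    if name in __all__:
        return import_module(f"ipb.{name}")
    raise AttributeError(f"module 'ipb' has no attribute {name!r}")
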