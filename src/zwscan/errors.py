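"""Exception hierarchy shared across the pipeline."""


class ZwscanError(Exception):
    """Base class for all pipeline errors."""


class PedigreeError(ZwscanError):
    """Pedigree violates family invariants (e.g. not exactly one mother/father)."""


class SampleMismatchError(ZwscanError):
    """Sample ids in the genotype file cannot be reconciled with the pedigree."""


class GenotypeParseError(ZwscanError):
    """Malformed genotype token or record; message names the offending line."""


class AlignmentError(ZwscanError):
    """Ragged alignment, unparseable sequence name, or tip/sequence mismatch."""


class HitTableParseError(ZwscanError):
    """Tabular hit file has the wrong shape; message names the line."""


class ConfigError(ZwscanError):
    """A simulation or filter configuration is internally inconsistent."""


class TraceError(ZwscanError):
    """A likelihood trace is empty or non-finite."""


class ChronogramError(ZwscanError):
    """A tree is not a usable chronogram (zero depth, not ultrametric)."""
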