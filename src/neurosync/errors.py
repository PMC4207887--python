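"""Exception hierarchy shared across the package."""


class NeuroSyncError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeuroSyncError):
    """A recording or annotation file violates the expected dialect."""


class ConfigError(NeuroSyncError):
    """An invalid parameter or parameter combination."""


class DetectionError(NeuroSyncError):
    """Event detection cannot proceed on the given signal."""


class QualityError(NeuroSyncError):
    """The EAdi signal fails the amplitude/breath-count quality gate."""

    def __init__(self, verdict):
        self.verdict = verdict
        super().__init__(verdict.reason)


class FitError(NeuroSyncError):
    """A regression fit failed to converge."""
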