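"""Exception hierarchy for the C-OCE pipeline."""


class CoceError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CoceError, ValueError):
    """A configuration or phantom parameter violates its invariants."""


class InputError(CoceError, ValueError):
    """Malformed runtime input (shape mismatch, empty sample, bad ROI...)."""


class AliasingError(CoceError, RuntimeError):
    """Interframe phase steps too large to be unwrapped reliably.

    Carries the list of offending frame-pair indices in ``pairs``.
    """

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            f"phase aliasing detected for frame pairs {self.pairs}; "
            "reduce the compression step between frames"
        )


class SegmentationError(CoceError, RuntimeError):
    """No depth band satisfying the reference-layer homogeneity rule."""


class CalibrationError(CoceError, RuntimeError):
    """No compression state reaches the standardized pressure window."""

    def __init__(self, achieved_kpa, target_kpa, tolerance_kpa):
        self.achieved_kpa = tuple(achieved_kpa)
        super().__init__(
            f"no compression step within {target_kpa} +/- {tolerance_kpa} kPa; "
            f"achieved silicone-inferred pressures span "
            f"{self.achieved_kpa[0]:.3g}-{self.achieved_kpa[1]:.3g} kPa"
        )


class SchemaError(CoceError, ValueError):
    """Cohort CSV rows violating the schema; carries (line, reason) pairs."""

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"line {ln}: {why}" for ln, why in self.problems)
        super().__init__(f"cohort schema violations: {lines}")
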