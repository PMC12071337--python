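"""Default parameterization of the nine marmoset TG electrophysiological groups.

Each entry holds the group-level mean and SEM for every measured parameter
(capacitance pF, RMP mV, AP width at base dB ms, falling-phase dV/dt hump
metric mV/ms, AHP80 ms, AHP peak mV, rheobase pA, evoked train rate Hz, and
for mechanically responsive groups the MA threshold µm, maximal MA current pA
and inactivation tau ms), the number of recorded neurons N, and the
falling-phase shape archetype.  Between-neuron spread is reconstructed as
SD = SEM * sqrt(N).

``clip`` bounds truncate per-neuron draws to each group's defining region:
the groups are *defined* by feature cutoffs (hump metric, dB, AHP80), so a
neuron drawn outside its group's region would contradict its own label.  The
bounds carry a small guard beyond the classifier cutoffs so that extraction
error on clean traces cannot cross a boundary.  RMP is kept below -36.5 mV
because the cohort emulates recordings that already passed quality control.
"""

DOUBLE_PEAK = "double_peak"
DEFLECTION = "deflection"
LINEAR = "linear"

# (mean, sem) pairs; None means not applicable for the group.
GROUP_TABLE = {
    "S1": dict(
        n=27,
        shape=DOUBLE_PEAK,
        cap=(68.9, 4.9),
        rmp=(-50.0, 1.7),
        db=(10.2, 0.6),
        hump=(-12.3, 1.2),
        ahp80=(28.7, 5.8),
        ahp_peak=(-9.3, 0.8),
        rheobase=None,
        train=None,
        train_fraction=0.0,
        ma=None,
    ),
    "S2": dict(
        n=29,
        shape=DOUBLE_PEAK,
        cap=(62.6, 3.7),
        rmp=(-56.4, 1.7),
        db=(8.1, 0.3),
        hump=(-12.6, 1.7),
        ahp80=(48.1, 7.5),
        ahp_peak=(-11.4, 0.7),
        rheobase=(125.9, 12.8),
        train=(8.4, 1.8),
        train_fraction=1.0,
        ma=None,
    ),
    "S3": dict(
        n=12,
        shape=DOUBLE_PEAK,
        cap=(59.1, 5.6),
        rmp=(-63.4, 3.5),
        db=(10.7, 1.1),
        hump=(-13.2, 1.4),
        ahp80=(32.7, 9.1),
        ahp_peak=(-7.5, 1.0),
        rheobase=(161.1, 20.0),
        train=(4.6, 0.8),
        train_fraction=1.0,
        ma=dict(threshold=(24.0, 1.4), max_amp=(105.8, 18.8), tau=(96.2, 28.7)),
    ),
    "S4": dict(
        n=15,
        shape=LINEAR,
        cap=(65.3, 6.2),
        rmp=(-38.3, 2.4),
        db=(7.6, 0.9),
        hump=None,
        ahp80=(8.0, 3.1),
        ahp_peak=(-5.5, 0.8),
        rheobase=None,
        train=None,
        train_fraction=0.0,
        ma=None,
    ),
    "M1": dict(
        n=32,
        shape=DEFLECTION,
        cap=(88.8, 4.1),
        rmp=(-62.8, 1.5),
        db=(5.1, 0.3),
        hump=(-0.6, 1.3),
        ahp80=(48.7, 7.1),
        ahp_peak=(-10.3, 0.9),
        rheobase=(173.0, 28.1),
        train=(8.4, 2.7),
        train_fraction=0.4,
        ma=None,
    ),
    "M2": dict(
        n=21,
        shape=DEFLECTION,
        cap=(104.4, 3.2),
        rmp=(-63.6, 1.5),
        db=(4.2, 0.4),
        hump=(0.3, 1.7),
        ahp80=(55.0, 11.3),
        ahp_peak=(-9.6, 1.2),
        rheobase=(175.0, 25.0),
        train=(5.5, 1.7),
        train_fraction=0.05,
        ma=dict(threshold=(22.7, 1.0), max_amp=(257.0, 34.0), tau=(78.4, 8.8)),
    ),
    "M3": dict(
        n=9,
        shape=LINEAR,
        cap=(80.9, 7.6),
        rmp=(-68.3, 1.9),
        db=(2.6, 0.1),
        hump=None,
        ahp80=(1.7, 0.9),
        ahp_peak=(-4.0, 0.4),
        rheobase=None,
        train=None,
        train_fraction=0.0,
        ma=dict(threshold=(19.0, 1.5), max_amp=(865.6, 150.2), tau=(40.7, 5.7)),
    ),
    "M4": dict(
        n=15,
        shape=LINEAR,
        cap=(81.7, 6.4),
        rmp=(-64.4, 1.0),
        db=(2.6, 0.1),
        hump=None,
        ahp80=(41.9, 10.6),
        ahp_peak=(-7.8, 0.9),
        rheobase=None,
        train=None,
        train_fraction=0.0,
        ma=dict(threshold=(17.4, 1.4), max_amp=(1636.0, 359.0), tau=(109.8, 44.1)),
    ),
    "M5": dict(
        n=25,
        shape=LINEAR,
        cap=(72.9, 4.8),
        rmp=(-59.0, 2.3),
        db=(2.3, 0.1),
        hump=None,
        ahp80=(11.8, 1.9),
        ahp_peak=(-9.4, 0.9),
        rheobase=None,
        train=None,
        train_fraction=0.0,
        ma=dict(threshold=(17.8, 1.4), max_amp=(1001.0, 231.5), tau=(54.0, 8.7)),
    ),
}

# Per-group truncation bounds for between-neuron draws (see module docstring).
GROUP_CLIPS = {
    "S1": dict(db=(5.2, 16.0), hump=(-40.0, -6.5), ahp80=(2.0, 120.0), ahp_peak=(-20.0, -2.0)),
    "S2": dict(db=(5.2, 16.0), hump=(-40.0, -6.5), ahp80=(2.0, 120.0), ahp_peak=(-20.0, -2.0)),
    "S3": dict(db=(5.2, 16.0), hump=(-40.0, -6.5), ahp80=(2.0, 120.0), ahp_peak=(-20.0, -2.0)),
    "S4": dict(db=(4.3, 16.0), ahp80=(1.0, 120.0), ahp_peak=(-15.0, -1.5)),
    "M1": dict(db=(3.0, 8.0), hump=(-1.2, -0.2), ahp80=(2.0, 120.0), ahp_peak=(-20.0, -2.0)),
    "M2": dict(db=(3.0, 8.0), hump=(-1.2, -0.2), ahp80=(2.0, 120.0), ahp_peak=(-20.0, -2.0)),
    "M3": dict(db=(1.2, 3.7), ahp80=(0.4, 4.5), ahp_peak=(-4.4, -0.8)),
    "M4": dict(db=(1.2, 3.7), ahp80=(23.0, 150.0), ahp_peak=(-20.0, -4.5)),
    "M5": dict(db=(1.2, 3.7), ahp80=(1.0, 17.5), ahp_peak=(-20.0, -6.0)),
}

COMMON_CLIPS = dict(
    cap=(15.0, 160.0),
    rmp=(-75.0, -36.5),
    rheobase=(60.0, 500.0),
    train=(3.5, 20.0),
    threshold=(4.0, 27.5),
    max_amp=(25.0, 4000.0),
    tau=(10.0, 280.0),
)

# Joint immunohistochemistry composition (percent of all neurons) for the
# CGRP x trpV1 panel, plus independently assessed single markers.
IHC_JOINT_PERCENT = {
    "cgrp_only": 30.3,  # CGRP+ / trpV1-
    "cgrp_trpv1": 28.4,  # CGRP+ / trpV1+
    "trpv1_only": 8.6,  # CGRP- / trpV1+
    "negative": 32.7,  # neither marker
}
IHC_SINGLE_PERCENT = {"MrgprD": 7.3, "PV": 20.1}
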