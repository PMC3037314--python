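import hypothesis

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

GAMMAS = {
    "gamma1": (8.0, 2.0),
    "gamma2": (15.0, 5.0),
    "gamma3": (8.0, 0.5),
    "gamma4": (15.0, 0.5),
}
D_GRID = [0.0, 1.0, 10.0, 100.0, 2000.0, 5e4]
N_CELLS = 100
R_RATIO = 1e-5
NR = N_CELLS * R_RATIO
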