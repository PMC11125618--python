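from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
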