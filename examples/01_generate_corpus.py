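"""Generate a synthetic cry corpus and inspect its design.

Builds the default study-emulation corpus (22 babies, 4 pain cries each, 18
babies with >= 6 discomfort cries) and prints the per-condition counts and
duration statistics.  Writing WAV + CSV to disk is optional.
"""

from crysig import generate_corpus, study_profile, write_corpus

cfg = study_profile(seed=1)
recordings, metadata = generate_corpus(cfg)

print(f"sequences: {len(recordings)}")
print(metadata.groupby("condition").size().to_string())
print(
    "duration: mean %.2f s, sd %.2f s"
    % (metadata.duration_s.mean(), metadata.duration_s.std())
)
counts = metadata[metadata.condition == "discomfort"].groupby("baby_id").size()
print(f"babies with >= 6 discomfort sequences: {(counts >= 6).sum()} / {len(counts)}")

# uncomment to write 16-bit WAVs and metadata.csv:
# write_corpus(recordings, metadata, "scratch/corpus")
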