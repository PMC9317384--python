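# Occipital electrode sets for the differential activity OL - OR.
# The 9+9 synthetic labels stand in for the study's unpublished
# 128-channel identities; supply your own lists for real recordings.
left: [OL1, OL2, OL3, OL4, OL5, OL6, OL7, OL8, OL9]
right: [OR1, OR2, OR3, OR4, OR5, OR6, OR7, OR8, OR9]
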