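survey,respondent,dead,frail,withdrawn,lost
2,0.839,0.045,0.008,0.047,0.061
3,0.696,0.099,0.026,0.090,0.090
4,0.576,0.184,0.044,0.109,0.087
5,0.447,0.284,0.051,0.114,0.104
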