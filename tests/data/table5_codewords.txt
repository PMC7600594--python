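BEEEEED ADECEEE ACDBCEE ADEEEEE EDEDEEE
BCDAECE BEEEEDD DDECEEE BCDBECE CEEEEED
DEEBEEE ADEBDDE DDEEDDD CEEBEEE DDEDEDE
DDEEDDD CEEAEEE CDECEEE EDDEDDD BEEAEEE
CDECEEE ECDEDDD BEEAEEE DDECEEE ECDEDDD
AEEAEEE DDECEEE EDDEDDD BEEAEEE DDECEEE
BDEAEEE BEEAEEE DDECEEE ECDEDDD AEEAEEE
BDEAEEE EBCECEC BEECDDE BDEBEBE CDEDDDD
AEEAEDE BEEBECE CDEDDDD AEEAEDE BDEAECE
EEEEDEE AEEAEEE BEEAEEE EEEEDEE BEEAEEE
CDEAEDE EEEEDEE AEEAEEE CDEAEDE DEEEDED
AEEAEEE BDEBEDE DEEEEEE AEEBEDE BDEBEDE
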