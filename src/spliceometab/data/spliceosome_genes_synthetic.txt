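SNRNP200
PRPF8
EFTUD2
USP39
SNRPB
SNRPD1
SNRPD2
SNRPD3
SNRPE
SNRPF
SNRPG
SF3A1
SF3A2
SF3A3
SF3B1
SF3B2
SF3B3
SF3B4
SF3B5
SF3B6
PRPF3
PRPF4
PRPF6
PRPF19
PRPF31
PRPF38A
PRPF40A
SNRNP40
SNRNP70
SNRPA
SNRPA1
SNRPB2
SNRPC
LSM2
LSM3
LSM4
LSM5
LSM6
LSM7
DDX23
CDC40
AQR
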