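>SspDnaE_N
CLSYMTEILTVLYAFLKIGKQVEKRIECTYYMVDNNGNIYTQVIMQWIGRGRQEDFEYQL
QDPSVIRATKDHKFKTPDHQMLPIVEIFSVEDDECRVDNRPNKGRMQGDCCLWWSLISAK
QHP
>SspDnaE_C
MITGATRKYLGKQNIYDIGFMRDHQHALNNPFFADN
>NpuDnaE_N
CLSYETEILTVEYGLLPIGKIVEKRIECTVYSVDNNGNIYTQPVAQWHDRGEQEVFEYCL
EDGSLIRATKDHKFMTVDGQMLPIDEIFERELDLMRVDNLPN
>NpuDnaE_C
MIKIATRKYLGKQNVYDIGVERDHNFALKNGFIASN
>AvaDnaE_N
CLSPETEILTVGYGLLAIGKIVEKKIECTVYSVDNNGNIKTQPVAQWHDRGELEVSEYCL
EDSSLIRYTKDHKFMTVDGQMYPIKEINERELDLTRVDNLPN
>AvaDnaE_C
MIKIAQRKYSGKQNVYWIKVERDHNFALKKGFISSN
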