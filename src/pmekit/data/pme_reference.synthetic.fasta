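>PME_REF_SYNTHETIC synthetic stand-in for the tomato PME structural reference; curated panel residues placed at their documented positions
VRSHWHCPKCVSWHAWKAERCFSDNQIEVTPDIMCRRPCCMMEFWEPNKLYHKADVLLWL
CQPECAEVSWLQSGDDHLVFFYADWRFDFQWPDHWNHRMEYNCNWWKSQLRRNCDNKTEG
YDYGDLDDILQDFYYSHMVPIHATAEAWPGYKDHWFRYAFRFDYVCEHCPNPICYFVMVV
IQSISCNDEKHDQGRNQHWHATQIYHLWMRWKMSLWNYQERDWVSCQRVTNNPWTPIEFE
EHGHFMHWFVPAKKVIIPHNWCFRRHSEWTLSLNGRNDVCGVHNNIRPCLVDFIYPHDWT
LPTPFHVYNITMTGDKWKNRIWLYHNWNDW
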