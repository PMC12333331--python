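&FCI NORB=4,NELEC=30,MS2=0,
 ORBSYM=1,1,1,1,
 ISYM=1,
&END
 3.7052734929541248E-01    1    1    1    1
-2.2230481344642783E-15    2    1    1    1
 9.2110556067967531E-02    2    1    2    1
 3.0664494456666613E-01    2    2    1    1
 9.4611818379775059E-15    2    2    2    1
 3.1782510745635456E-01    2    2    2    2
-5.8300474531854544E-02    3    1    1    1
 7.9502376904017069E-15    3    1    2    1
 9.9436249724956776E-03    3    1    2    2
 6.2496597287431080E-02    3    1    3    1
 1.1568003499551338E-14    3    2    1    1
 6.7365258734909811E-02    3    2    2    1
 1.7062740109707875E-14    3    2    2    2
 4.2413988987632933E-16    3    2    3    1
 1.0181194969440285E-01    3    2    3    2
 3.0625062839720912E-01    3    3    1    1
-6.6578687007989856E-15    3    3    2    1
 3.0898874688666284E-01    3    3    2    2
 2.3721766417979587E-03    3    3    3    1
-1.5515366769136563E-14    3    3    3    2
 3.0964182994857559E-01    3    3    3    3
 2.7460672624712856E-15    4    1    1    1
 2.9669534155406029E-02    4    1    2    1
-8.4853998827405519E-15    4    1    2    2
-8.6272135269016559E-15    4    1    3    1
-3.0636268137603208E-02    4    1    3    2
 9.6797569959505836E-15    4    1    3    3
 6.5019998206940294E-02    4    1    4    1
 5.2545733038817155E-02    4    2    1    1
-1.5006225428937370E-14    4    2    2    1
-3.0255205390387566E-03    4    2    2    2
-5.1725917287013395E-02    4    2    3    1
 8.8731105796213683E-16    4    2    3    2
-3.7067399721881621E-03    4    2    3    3
-3.9091993531137348E-15    4    2    4    1
 4.9630712970740551E-02    4    2    4    2
-1.7394072293619445E-14    4    3    1    1
-7.7173001872578501E-02    4    3    2    1
-5.6291776795447390E-15    4    3    2    2
 1.3189102587851664E-14    4    3    3    1
-5.7723677562030923E-02    4    3    3    2
 6.7983813023531070E-15    4    3    3    3
-2.7872320291325341E-02    4    3    4    1
-4.3177267317062729E-15    4    3    4    2
 7.3083336978206973E-02    4    3    4    3
 3.4318178962481627E-01    4    4    1    1
-1.0842021724855044E-14    4    4    2    1
 2.9002289771429546E-01    4    4    2    2
-5.0430043485615195E-02    4    4    3    1
-3.8302694349567901E-15    4    4    3    2
 2.9052671907305838E-01    4    4    3    3
 6.6682770416548465E-15    4    4    4    1
 4.8120711552330830E-02    4    4    4    2
-7.8895223687425187E-15    4    4    4    3
 3.3108149215914395E-01    4    4    4    4
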