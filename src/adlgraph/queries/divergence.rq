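# Fires for each target activity that contains at least one observation on
# each of the three protocol devices and for which at least one combination
# (e1 on device 1, e2 on device 2, e3 on device 3) violates t1 < t2 < t3.
PREFIX adl: <http://example.org/adl/ontology#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>

CONSTRUCT {
  ?problem a adl:DivergenceFromProtocol ;
           adl:isProblemOf ?patient ;
           adl:problem_date ?start ;
           adl:problematicActivity ?activity .
}
WHERE {
  ?activity a adl:Activity ;
            adl:activity_pk ?activity_pk ;
            adl:activity_start ?start ;
            adl:activity_name ${activity_name} ;
            adl:refersToUser ?patient .
  FILTER EXISTS {
    ?activity adl:consistsOf ?event1 .
    ?event1 adl:observation_start_time ?time1 ;
            adl:refersToDevice ?device1 .
    ?device1 adl:device_name ${device_1} .
    ?activity adl:consistsOf ?event2 .
    ?event2 adl:observation_start_time ?time2 ;
            adl:refersToDevice ?device2 .
    ?device2 adl:device_name ${device_2} .
    ?activity adl:consistsOf ?event3 .
    ?event3 adl:observation_start_time ?time3 ;
            adl:refersToDevice ?device3 .
    ?device3 adl:device_name ${device_3} .
    FILTER( !( ?time1 < ?time2 && ?time2 < ?time3 ) )
  }
  BIND( IRI(CONCAT("${resource_base}problem/divergence/",
                   ENCODE_FOR_URI(?activity_pk))) AS ?problem )
}
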